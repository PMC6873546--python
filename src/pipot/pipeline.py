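"""The end-to-end synthetic study: natives -> potential -> selection -> decoys.

This wires every stage together on generated data: compact self-avoiding
chains act as native structures, a knowledge-based potential is trained on
them, the TE matrix and principal-interaction selection are computed, and
the full and principal-only models are evaluated on Gaussian-perturbation
decoy ladders.

Defaults are chosen for chains of single-center residues with random
sequences: a 6 A cutoff with 1.0 A bins concentrates the scoring range on
the native-populated shell; the uniform distance reference (power-law with
exponent 0) makes occupied native bins favorable and the empty short-range
region repulsive, which is the signal coordinate-noise decoys probe; and a
pseudocount of 1.0 damps per-cell sampling noise at this training-set size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decoy_eval import evaluate_collection
from .energy_vectors import build_te_matrix, center_columns
from .pca_selection import SelectionResult, select_principal
from .potential import DistanceBinning, KnowledgeBasedPotential, ReferenceState
from .reduced_scoring import InteractionMask
from .structure_io import ContactScheme
from .synthetic import ChainSpec, DecoyLadderSpec, generate_chain, generate_decoy_ladder


@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions for the synthetic pipeline."""

    n_natives: int = 20
    chain_length: int = 30
    n_targets: int = 10
    n_decoys: int = 20
    noise_min: float = 2.0
    noise_max: float = 6.0
    cutoff: float = 6.0
    bin_width: float = 1.0
    reference_alpha: float = 0.0
    pseudocount: float = 1.0
    variance_threshold: float = 80.0


@dataclass
class PipelineResult:
    potential: KnowledgeBasedPotential
    selection: SelectionResult
    full_report: dict
    principal_report: dict
    full_per_target: "object"
    principal_per_target: "object"


def run_synthetic_pipeline(seed: int = 0, config: PipelineConfig | None = None) -> PipelineResult:
    """Generate natives, train, select principal interactions, evaluate decoys.

    Deterministic for a given seed: all generator seeds are spawned from it.
    Decoy ladders are built on the first ``n_targets`` natives.
    """
    cfg = config or PipelineConfig()
    ss = np.random.SeedSequence(seed)
    chain_seeds, ladder_seeds = (
        s.generate_state(n) % 2**31
        for s, n in zip(ss.spawn(2), (cfg.n_natives, cfg.n_targets))
    )
    natives = [
        generate_chain(ChainSpec(length=cfg.chain_length, seed=int(s)), f"native-{i:03d}")
        for i, s in enumerate(chain_seeds)
    ]
    scheme = ContactScheme(cutoff=cfg.cutoff, min_seq_sep=0, atom_mode="single-center")
    kbp = KnowledgeBasedPotential(
        scheme=scheme,
        binning=DistanceBinning(0.0, cfg.cutoff, cfg.bin_width),
        reference=ReferenceState("power-law", cfg.reference_alpha),
        pseudocount=cfg.pseudocount,
    ).fit(natives)
    te = build_te_matrix(natives, kbp.table_)
    selection = select_principal(center_columns(te), cfg.variance_threshold)
    noise = tuple(np.linspace(cfg.noise_min, cfg.noise_max, cfg.n_decoys))
    sets = [
        generate_decoy_ladder(natives[t], DecoyLadderSpec(noise, seed=int(ladder_seeds[t])))
        for t in range(cfg.n_targets)
    ]
    full_df, full_agg = evaluate_collection(sets, kbp.table_)
    mask = InteractionMask(frozenset(selection.principal_set), source="pipeline selection")
    pr_df, pr_agg = evaluate_collection(sets, kbp.table_, mask)
    return PipelineResult(kbp, selection, full_agg, pr_agg, full_df, pr_df)
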