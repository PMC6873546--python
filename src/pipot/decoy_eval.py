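"""Decoy-set evaluation: the six performance criteria and the success curve.

A decoy set is a native structure plus alternative conformations of the same
sequence.  A scoring function is judged by whether it ranks the native lowest
(Top1), how far the native sits below the decoy score distribution (Z-score),
the accuracy of its minimum-energy pick (RMSD of the minimum), the
energy-RMSD correlation (PC), the overlap of its best-scoring 20% with the
most accurate 20% of decoys (fraction enrichment, range 0-5), and the Z-score
of the lowest-RMSD ("best") decoy with native and best decoy excluded from
the reference distribution (Z-score_b).

The metric primitives below operate on plain score/RMSD arrays so they can be
checked independently of any structural machinery; the evaluate_* helpers
wire them to structures and a trained potential.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .energy_vectors import interaction_energy_vector
from .potential import PotentialTable
from .reduced_scoring import InteractionMask, pi_fraction
from .structure_io import Structure, calpha_rmsd, read_pdb

logger = logging.getLogger(__name__)


@dataclass
class DecoySet:
    target_id: str
    native: Structure
    decoys: list[tuple[Structure, float | None]]  # (structure, provided RMSD)

    def rmsds(self) -> np.ndarray:
        """Per-decoy C-alpha RMSD to the native; provided values take precedence."""
        out = []
        for s, provided in self.decoys:
            out.append(provided if provided is not None else calpha_rmsd(self.native, s))
        return np.asarray(out, dtype=float)


def load_decoy_set(directory, target_id: str | None = None, chain: str | None = None) -> DecoySet:
    """Load ``<dir>/native.pdb`` plus every other ``*.pdb`` as decoys.

    An optional ``rmsd.tsv`` (columns: decoy filename, C-alpha RMSD) overrides
    the internally computed RMSDs.
    """
    directory = Path(directory)
    native_path = directory / "native.pdb"
    if not native_path.exists():
        raise FileNotFoundError(f"{native_path} not found")
    tid = target_id or directory.name
    native = read_pdb(native_path, chain=chain, structure_id=f"{tid}/native")
    provided: dict[str, float] = {}
    rmsd_file = directory / "rmsd.tsv"
    if rmsd_file.exists():
        df = pd.read_csv(rmsd_file, sep="\t", header=None, names=["file", "rmsd"])
        provided = dict(zip(df["file"].astype(str), df["rmsd"].astype(float)))
    decoys = []
    for p in sorted(directory.glob("*.pdb")):
        if p.name == "native.pdb":
            continue
        s = read_pdb(p, chain=chain, structure_id=f"{tid}/{p.stem}")
        decoys.append((s, provided.get(p.name)))
    return DecoySet(tid, native, decoys)


# ---------------------------------------------------------------- metrics

def top1(native_score: float, decoy_scores: np.ndarray) -> bool:
    """True iff the native score is strictly the lowest."""
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    best = decoy_scores.min()
    if native_score == best:
        logger.warning("native tied with best decoy; counted as failure")
        return False
    return bool(native_score < best)


def zscore_native(native_score: float, decoy_scores: np.ndarray) -> float:
    """(mean(decoys) - native) / sd(decoys); positive when the native is better."""
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    if len(decoy_scores) < 2:
        raise ValueError("need at least 2 decoys for a Z-score")
    sd = decoy_scores.std(ddof=1)
    if sd == 0:
        raise ValueError("zero decoy score standard deviation")
    return float((decoy_scores.mean() - native_score) / sd)


def rmsd_of_minimum(
    native_score: float, decoy_scores: np.ndarray, decoy_rmsds: np.ndarray
) -> float:
    """RMSD (to native) of the minimum-energy structure; 0 if that's the native."""
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    decoy_rmsds = np.asarray(decoy_rmsds, dtype=float)
    best = decoy_scores.min()
    if native_score <= best:
        if native_score == best:
            logger.warning("native tied with best decoy score; native reported")
        return 0.0
    tied = np.nonzero(decoy_scores == best)[0]
    if len(tied) > 1:
        logger.warning("score tie among %d decoys; lowest RMSD reported", len(tied))
    return float(decoy_rmsds[tied].min())


def pearson_energy_rmsd(decoy_scores: np.ndarray, decoy_rmsds: np.ndarray) -> float:
    """Pearson r between decoy energies and their RMSDs (native excluded)."""
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    decoy_rmsds = np.asarray(decoy_rmsds, dtype=float)
    if len(decoy_scores) < 3:
        raise ValueError("need at least 3 decoys for a correlation")
    if decoy_scores.std() == 0 or decoy_rmsds.std() == 0:
        raise ValueError("zero variance in scores or RMSDs")
    return float(stats.pearsonr(decoy_scores, decoy_rmsds).statistic)


def fraction_enrichment(decoy_scores: np.ndarray, decoy_rmsds: np.ndarray) -> float:
    """Overlap of top-20%-by-RMSD and top-20%-by-score decoys vs random; in [0, 5]."""
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    decoy_rmsds = np.asarray(decoy_rmsds, dtype=float)
    n = len(decoy_scores)
    if n < 5:
        raise ValueError("need at least 5 decoys for fraction enrichment")
    k = max(1, int(np.floor(0.2 * n)))
    by_rmsd = set(np.argsort(decoy_rmsds, kind="stable")[:k])
    by_score = set(np.argsort(decoy_scores, kind="stable")[:k])
    # overlap / (0.2 * 0.2 * n), written to be exact in floating point
    return len(by_rmsd & by_score) * 25.0 / n


def zscore_best(decoy_scores: np.ndarray, decoy_rmsds: np.ndarray) -> float:
    """Z-score of the lowest-RMSD decoy against the remaining decoys.

    The best decoy is identified by RMSD (not score); it and the native are
    excluded from the reference mean and sample standard deviation.
    """
    decoy_scores = np.asarray(decoy_scores, dtype=float)
    decoy_rmsds = np.asarray(decoy_rmsds, dtype=float)
    if len(decoy_scores) < 3:
        raise ValueError("need at least 3 decoys")
    order = np.argsort(decoy_rmsds, kind="stable")
    candidates = np.nonzero(decoy_rmsds == decoy_rmsds[order[0]])[0]
    best = int(candidates[0])
    rest = np.delete(decoy_scores, best)
    sd = rest.std(ddof=1)
    if sd == 0:
        raise ValueError("zero score standard deviation among remaining decoys")
    return float((rest.mean() - decoy_scores[best]) / sd)


# ---------------------------------------------------------- evaluation

@dataclass
class TargetReport:
    target_id: str
    top1: bool
    zscore: float
    rmsd_min: float
    pc: float
    fe: float
    zscore_b: float
    pi_mean: float
    pi_sd: float
    n_decoys: int


def score_decoy_set(
    ds: DecoySet, table: PotentialTable, mask: InteractionMask | None = None
) -> tuple[float, np.ndarray]:
    """Native and decoy energies under the full or masked model."""
    keep = mask.indices(table.index) if mask is not None else None

    def _score(s: Structure) -> float:
        v = interaction_energy_vector(s, table).values
        return float(v.sum() if keep is None else v[keep].sum())

    return _score(ds.native), np.asarray([_score(s) for s, _ in ds.decoys])


def evaluate_decoy_set(
    ds: DecoySet, table: PotentialTable, mask: InteractionMask | None = None
) -> TargetReport:
    """All six criteria (plus the PI fraction) for one target."""
    native_score, decoy_scores = score_decoy_set(ds, table, mask)
    rmsds = ds.rmsds()
    pi_mask = mask if mask is not None else InteractionMask.full(table.index)
    pis = np.asarray(
        [pi_fraction(s, table, pi_mask) for s, _ in ds.decoys], dtype=float
    )
    return TargetReport(
        target_id=ds.target_id,
        top1=top1(native_score, decoy_scores),
        zscore=zscore_native(native_score, decoy_scores),
        rmsd_min=rmsd_of_minimum(native_score, decoy_scores, rmsds),
        pc=pearson_energy_rmsd(decoy_scores, rmsds),
        fe=fraction_enrichment(decoy_scores, rmsds),
        zscore_b=zscore_best(decoy_scores, rmsds),
        pi_mean=float(pis.mean()),
        pi_sd=float(pis.std(ddof=1)) if len(pis) > 1 else 0.0,
        n_decoys=len(ds.decoys),
    )


def evaluate_collection(
    sets: list[DecoySet], table: PotentialTable, mask: InteractionMask | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-target reports and Table-style aggregates over a decoy collection."""
    if not sets:
        raise ValueError("empty decoy collection")
    reports = []
    for ds in sets:
        try:
            reports.append(evaluate_decoy_set(ds, table, mask))
        except ValueError as exc:
            logger.warning("skipping target %s: %s", ds.target_id, exc)
    if not reports:
        raise ValueError("no target could be evaluated")
    df = pd.DataFrame([vars(r) for r in reports]).set_index("target_id")
    aggregates = {
        "n_targets": len(df),
        "top1": int(df["top1"].sum()),
        "zscore": float(df["zscore"].mean()),
        "rmsd_min": float(df["rmsd_min"].mean()),
        "pc": float(df["pc"].mean()),
        "fe": float(df["fe"].mean()),
        "zscore_b": float(df["zscore_b"].mean()),
        "pi_mean": float(df["pi_mean"].mean()),
        "pi_sd": float(df["pi_mean"].std(ddof=1)) if len(df) > 1 else 0.0,
    }
    return df, aggregates


def success_curve(
    sets: list[DecoySet],
    table: PotentialTable,
    ranking: list[str],
    ks: list[int] | None = None,
) -> pd.DataFrame:
    """Top1 count using only the top-k ranked pair types, for k = 1..p.

    Because the total energy is linear over pair types, the energy under the
    top-k mask is a cumulative sum over ranking-ordered energy-vector
    entries, so the whole curve costs one energy vector per structure.
    """
    labels = table.index.labels
    if sorted(ranking) != sorted(labels):
        raise ValueError("ranking must cover every pair type exactly once")
    cols = np.asarray([table.index.index_of_label(lbl) for lbl in ranking])
    p = len(cols)
    ks = list(ks) if ks is not None else list(range(1, p + 1))
    counts = np.zeros(len(ks), dtype=int)
    for ds in sets:
        nat = np.cumsum(interaction_energy_vector(ds.native, table).values[cols])
        dec = np.vstack(
            [np.cumsum(interaction_energy_vector(s, table).values[cols]) for s, _ in ds.decoys]
        )
        for i, k in enumerate(ks):
            counts[i] += int(nat[k - 1] < dec[:, k - 1].min())
    return pd.DataFrame({"k": ks, "top1": counts})
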