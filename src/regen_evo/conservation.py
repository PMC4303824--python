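"""Inter-clade amino-acid conservation profiles.

For each of the three clade-pair comparisons (fp, mf, mp) the profile
is built in three steps:

1. gap filtering — alignment columns containing a gap (or an 'X') in
   any row are dropped, so all three profiles share one x-axis;
2. raw scoring — at each kept column every residue of one clade is
   compared against every residue of the other clade with BLOSUM62 and
   the scores are averaged (the per-column dispersion is kept too);
3. smoothing — the raw signal x is low-pass filtered with the one-pole
   recursion y_n = alpha * x_n + (1 - alpha) * y_{n-1}. The filter is
   directional, so it is run forward and on the reversed signal and the
   two outputs are averaged elementwise.

A small alpha smooths aggressively (long memory); alpha -> 1 returns
the raw signal. The default alpha is 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from regen_evo.seqio import GAP, PAIR_CODES, CladeMap, ProteinAlignment

__all__ = [
    "ConservationProfile",
    "ConservationCall",
    "load_matrix",
    "gap_filter",
    "column_score",
    "low_pass",
    "bidirectional_profile",
    "profile_contrast",
    "profiles_to_frame",
    "plot_profiles",
]

DEFAULT_ALPHA = 0.05

_UNSCORABLE = {GAP, "X", "*"}


def load_matrix(name: str = "BLOSUM62"):
    """Load a substitution matrix by name from Biopython's collection."""
    return substitution_matrices.load(name)


@dataclass
class ConservationProfile:
    """Per clade-pair conservation signal over gap-filtered columns."""

    clade_pair: tuple[str, str]
    code: str
    raw: np.ndarray
    dispersion: np.ndarray
    smoothed_fwd: np.ndarray
    smoothed_rev: np.ndarray
    smoothed_avg: np.ndarray
    alpha: float
    kept_columns: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.kept_columns)
        for name in ("raw", "dispersion", "smoothed_fwd", "smoothed_rev", "smoothed_avg"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from kept_columns")


@dataclass(frozen=True)
class ConservationCall:
    """Profile-contrast verdict: which clade pair is more conserved."""

    verdict: str  # "ToL-like" | "non-ToL" | "indeterminate"
    margin: float  # mean(fp smoothed) - mean(mf smoothed)
    mean_fp: float
    mean_mf: float


def gap_filter(aln: ProteinAlignment, policy: str = "any-gap") -> np.ndarray:
    """Return ascending 0-based indices of columns kept for scoring.

    Under the default "any-gap" policy a column is kept iff no row has
    a gap or an unscorable residue ('X', '*') in it. An empty result is
    allowed but warned about.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    if policy != "any-gap":
        raise ValueError(f"unknown gap policy {policy!r}")
    rows = list(aln.rows.values())
    kept = [
        i
        for i in range(aln.length)
        if not any(r[i] in _UNSCORABLE for r in rows)
    ]
    if not kept:
        warnings.warn("gap filter removed every alignment column", stacklevel=2)
    return np.asarray(kept, dtype=int)


def _encode(aln: ProteinAlignment, ids: list[str], matrix) -> np.ndarray:
    """Encode rows as indices into the matrix alphabet; -1 = unscorable."""
    lookup = {aa: i for i, aa in enumerate(matrix.alphabet)}
    out = np.full((len(ids), aln.length), -1, dtype=np.int16)
    for r, sid in enumerate(ids):
        for c, aa in enumerate(aln.rows[sid]):
            if aa not in _UNSCORABLE:
                out[r, c] = lookup.get(aa, -1)
    return out


def column_score(
    aln: ProteinAlignment,
    column: int,
    clade_a_ids: list[str],
    clade_b_ids: list[str],
    matrix=None,
) -> tuple[float, float]:
    """All-pairs mean and population SD of substitution-matrix scores.

    Every residue of clade A at ``column`` is compared with every
    residue of clade B; the |A| x |B| scores are averaged. The column
    must be gap-free for both clades.
    """
    if not clade_a_ids or not clade_b_ids:
        raise ValueError("empty clade in column_score")
    matrix = load_matrix() if matrix is None else matrix
    res_a = [aln.rows[i][column] for i in clade_a_ids]
    res_b = [aln.rows[i][column] for i in clade_b_ids]
    bad = [r for r in res_a + res_b if r in _UNSCORABLE]
    if bad:
        raise ValueError(f"unscorable residue {bad[0]!r} at column {column}")
    scores = np.array([[matrix[a, b] for b in res_b] for a in res_a], dtype=float)
    return float(scores.mean()), float(scores.std())


def low_pass(x, alpha: float, y0: float | None = None) -> np.ndarray:
    """One-pole exponential low-pass: y_n = alpha*x_n + (1-alpha)*y_{n-1}.

    ``y0`` seeds the recursion (the value of y_{-1}); by default it is
    x_0, which avoids a startup transient. alpha must lie in (0, 1).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input signal")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    y = np.empty_like(x)
    prev = float(x[0]) if y0 is None else float(y0)
    for n, xn in enumerate(x):
        prev = alpha * xn + (1.0 - alpha) * prev
        y[n] = prev
    return y


def bidirectional_profile(
    aln: ProteinAlignment,
    clade_map: CladeMap,
    matrix=None,
    alpha: float = DEFAULT_ALPHA,
    gap_policy: str = "any-gap",
) -> dict[str, ConservationProfile]:
    """Compute the three clade-pair profiles (keys "fp", "mf", "mp").

    For each pair: raw per-column all-pairs mean score over gap-filtered
    columns, its dispersion, the forward and reverse low-pass filtered
    signals, and their elementwise average.
    """
    matrix = load_matrix() if matrix is None else matrix
    clade_map.require_three_clades(aln.ids)
    kept = gap_filter(aln, gap_policy)
    profiles: dict[str, ConservationProfile] = {}
    mat = np.asarray(matrix, dtype=float)
    for code, (ia, ib) in PAIR_CODES.items():
        clade_a = clade_map.clade_order[ia]
        clade_b = clade_map.clade_order[ib]
        ids_a = [i for i in aln.ids if clade_map.entries.get(i) == clade_a]
        ids_b = [i for i in aln.ids if clade_map.entries.get(i) == clade_b]
        enc_a = _encode(aln, ids_a, matrix)[:, kept] if kept.size else np.empty((len(ids_a), 0), int)
        enc_b = _encode(aln, ids_b, matrix)[:, kept] if kept.size else np.empty((len(ids_b), 0), int)
        raw = np.empty(kept.size)
        sd = np.empty(kept.size)
        for j in range(kept.size):
            block = mat[np.ix_(enc_a[:, j], enc_b[:, j])]
            raw[j] = block.mean()
            sd[j] = block.std()
        if kept.size:
            fwd = low_pass(raw, alpha)
            rev = low_pass(raw[::-1], alpha)[::-1]
            avg = 0.5 * (fwd + rev)
        else:
            fwd = rev = avg = raw.copy()
        profiles[code] = ConservationProfile(
            clade_pair=(clade_a, clade_b),
            code=code,
            raw=raw,
            dispersion=sd,
            smoothed_fwd=fwd,
            smoothed_rev=rev,
            smoothed_avg=avg,
            alpha=alpha,
            kept_columns=kept,
        )
    return profiles


def profile_contrast(
    profiles: dict[str, ConservationProfile], delta: float = 0.0
) -> ConservationCall:
    """Contrast the fp and mf profiles into a per-gene verdict.

    non-ToL iff mean(fp) - mean(mf) > delta (fungi look closer to plants
    than to metazoans); ToL-like iff mean(mf) - mean(fp) > delta; else
    indeterminate. Means are taken over the averaged smoothed signal.
    """
    fp, mf = profiles["fp"], profiles["mf"]
    if fp.kept_columns.size == 0:
        warnings.warn("no kept columns: conservation verdict indeterminate", stacklevel=2)
        return ConservationCall("indeterminate", float("nan"), float("nan"), float("nan"))
    mean_fp = float(fp.smoothed_avg.mean())
    mean_mf = float(mf.smoothed_avg.mean())
    margin = mean_fp - mean_mf
    if margin > delta:
        verdict = "non-ToL"
    elif -margin > delta:
        verdict = "ToL-like"
    else:
        verdict = "indeterminate"
    return ConservationCall(verdict, margin, mean_fp, mean_mf)


def profiles_to_frame(profiles: dict[str, ConservationProfile]) -> pd.DataFrame:
    """Tidy per-column table of all three profiles."""
    frames = []
    for code, p in profiles.items():
        frames.append(
            pd.DataFrame(
                {
                    "column_index": p.kept_columns,
                    "clade_pair": code,
                    "raw": p.raw,
                    "sd": p.dispersion,
                    "smoothed_fwd": p.smoothed_fwd,
                    "smoothed_rev": p.smoothed_rev,
                    "smoothed_avg": p.smoothed_avg,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


#: Line colors for the three comparisons (fp cyan, mf magenta).
PAIR_COLORS = {"fp": "c", "mf": "m", "mp": "y"}


def plot_profiles(profiles: dict[str, ConservationProfile], path: str) -> None:
    """Line plot of the averaged smoothed profiles (fp cyan, mf magenta)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 4))
    for code, p in profiles.items():
        ax.plot(
            np.arange(len(p.smoothed_avg)),
            p.smoothed_avg,
            color=PAIR_COLORS.get(code),
            label=f"{code} ({p.clade_pair[0]} x {p.clade_pair[1]})",
        )
    ax.set_xlabel("alignment position (gap-filtered)")
    ax.set_ylabel("mean substitution score (smoothed)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
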