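"""Pairwise Ka/Ks by Nei-Gojobori (1986) counting on codon alignments.

Synonymous and non-synonymous *sites* are counted per codon by
enumerating all nine single-nucleotide mutants (mutants that create a
stop codon are excluded from the denominator at that position);
*differences* between two codons are classified by averaging over all
orderings of the mutational steps, excluding pathways that pass through
a stop codon. Proportions are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p), which is undefined for
p >= 3/4: such comparisons are flagged saturated rather than given a
number, mirroring what deep (~1 Gya) clade splits do to Ks.

All 61 sense-codon site counts and all 61 x 61 difference counts are
precomputed once, so whole-alignment tables are table lookups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from math import log

import numpy as np
import pandas as pd

from regen_evo.seqio import (
    GAP_CODON,
    PAIR_CODES,
    SENSE_CODONS,
    STOP_CODONS,
    CladeMap,
    CodonAlignment,
    _CODON_TABLE,
)

__all__ = [
    "KaKsResult",
    "CladePairStats",
    "KaKsTable",
    "KaKsCall",
    "count_sites",
    "count_differences",
    "pairwise_kaks",
    "clade_average",
    "kaks_contrast",
    "bootstrap_ka_contrast",
    "jukes_cantor",
]

_BASES = "ACGT"
_CODON_INDEX = {
    a + b + c: 16 * i + 4 * j + k
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
_ALL_CODONS = sorted(_CODON_INDEX, key=_CODON_INDEX.get)


def count_sites(codon: str) -> tuple[float, float]:
    """Synonymous and non-synonymous site counts of one sense codon.

    Each codon position contributes one site, split according to the
    fraction of its non-stop single-nucleotide mutants that are
    synonymous. The two counts always sum to 3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    if codon not in _CODON_TABLE:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    aa = _CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        n_syn = n_valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut in STOP_CODONS:
                continue
            n_valid += 1
            if _CODON_TABLE[mut] == aa:
                n_syn += 1
        if n_valid:
            syn += n_syn / n_valid
    return syn, 3.0 - syn


def _pathway_steps(codon_a: str, codon_b: str, order: tuple[int, ...]):
    """Yield (from, to) codons along one mutational ordering."""
    cur = list(codon_a)
    for pos in order:
        nxt = cur.copy()
        nxt[pos] = codon_b[pos]
        yield "".join(cur), "".join(nxt)
        cur = nxt


def count_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous and non-synonymous difference counts between two codons.

    For k differing positions the k! orderings of the mutational steps
    are averaged; orderings whose intermediate codons are stops are
    excluded and the average renormalized over the rest. The counts sum
    to k. If every ordering passes through a stop (which cannot happen
    between sense codons differing at <= 2 positions), all orderings are
    used with stop-passing steps classified as non-synonymous.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    for c in (codon_a, codon_b):
        if c in STOP_CODONS or c not in _CODON_TABLE:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff_pos = tuple(i for i in range(3) if codon_a[i] != codon_b[i])
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    valid_syn: list[float] = []
    all_syn: list[float] = []
    for order in permutations(diff_pos):
        syn = 0.0
        through_stop = False
        for src, dst in _pathway_steps(codon_a, codon_b, order):
            if dst in STOP_CODONS or src in STOP_CODONS:
                through_stop = True
            elif _CODON_TABLE[src] == _CODON_TABLE[dst]:
                syn += 1.0
        all_syn.append(syn)
        if not through_stop:
            valid_syn.append(syn)
    pool = valid_syn if valid_syn else all_syn
    mean_syn = sum(pool) / len(pool)
    return mean_syn, k - mean_syn


def _build_tables() -> dict[str, np.ndarray]:
    syn_sites = np.full(64, np.nan)
    nonsyn_sites = np.full(64, np.nan)
    sense = np.zeros(64, dtype=bool)
    for codon in SENSE_CODONS:
        i = _CODON_INDEX[codon]
        syn_sites[i], nonsyn_sites[i] = count_sites(codon)
        sense[i] = True
    syn_diffs = np.full((64, 64), np.nan)
    nonsyn_diffs = np.full((64, 64), np.nan)
    for ca in SENSE_CODONS:
        for cb in SENSE_CODONS:
            i, j = _CODON_INDEX[ca], _CODON_INDEX[cb]
            syn_diffs[i, j], nonsyn_diffs[i, j] = count_differences(ca, cb)
    return {
        "syn_sites": syn_sites,
        "nonsyn_sites": nonsyn_sites,
        "syn_diffs": syn_diffs,
        "nonsyn_diffs": nonsyn_diffs,
        "sense": sense,
    }


_TABLES: dict[str, np.ndarray] | None = None


def _tables() -> dict[str, np.ndarray]:
    global _TABLES
    if _TABLES is None:
        _TABLES = _build_tables()
    return _TABLES


def jukes_cantor(p: float) -> tuple[float, bool]:
    """JC-corrected distance and saturation flag for a proportion p."""
    arg = 1.0 - (4.0 / 3.0) * p
    if arg <= 0.0:
        return float("nan"), True
    return -0.75 * log(arg), False


@dataclass(frozen=True)
class KaKsResult:
    """NG86 estimates for one sequence pair."""

    ka: float  # nan if saturated
    ks: float  # nan if saturated
    ka_saturated: bool
    ks_saturated: bool
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    compared_codons: int

    @property
    def ka_ks(self) -> float:
        if self.ka_saturated or self.ks_saturated or self.ks == 0.0:
            return float("nan")
        return self.ka / self.ks


def _encode_codons(aln: CodonAlignment) -> tuple[list[str], np.ndarray]:
    """Encode rows as sense-codon indices; -1 marks gap/stop/ambiguous."""
    ids = aln.ids
    n = aln.n_codons
    out = np.full((len(ids), n), -1, dtype=np.int16)
    for r, sid in enumerate(ids):
        row = aln.rows[sid]
        for c in range(n):
            codon = row[3 * c : 3 * c + 3]
            if codon != GAP_CODON:
                idx = _CODON_INDEX.get(codon, -1)
                if idx >= 0 and _tables()["sense"][idx]:
                    out[r, c] = idx
    return ids, out


def _kaks_from_encoded(row_a: np.ndarray, row_b: np.ndarray) -> KaKsResult:
    t = _tables()
    valid = (row_a >= 0) & (row_b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable codons between the two rows")
    a, b = row_a[valid], row_b[valid]
    ss = float(0.5 * (t["syn_sites"][a] + t["syn_sites"][b]).sum())
    ns = float(0.5 * (t["nonsyn_sites"][a] + t["nonsyn_sites"][b]).sum())
    sd = float(t["syn_diffs"][a, b].sum())
    nd = float(t["nonsyn_diffs"][a, b].sum())
    p_s = sd / ss if ss > 0 else 0.0
    p_n = nd / ns if ns > 0 else 0.0
    ks, ks_sat = jukes_cantor(p_s)
    ka, ka_sat = jukes_cantor(p_n)
    return KaKsResult(
        ka=ka,
        ks=ks,
        ka_saturated=ka_sat,
        ks_saturated=ks_sat,
        syn_sites=ss,
        nonsyn_sites=ns,
        syn_diffs=sd,
        nonsyn_diffs=nd,
        compared_codons=n,
    )


def pairwise_kaks(row_a: str, row_b: str) -> KaKsResult:
    """NG86 Ka/Ks between two equal-length codon rows.

    Codon columns where either row has a gap, stop or ambiguity are
    skipped. Raises if no comparable codons remain.
    """
    if len(row_a) != len(row_b):
        raise ValueError("codon rows differ in length")
    aln = CodonAlignment({"a": row_a.upper(), "b": row_b.upper()})
    _, enc = _encode_codons(aln)
    return _kaks_from_encoded(enc[0], enc[1])


@dataclass(frozen=True)
class CladePairStats:
    mean_ka: float
    mean_ks: float
    n_pairs: int
    n_saturated: int  # pairs with saturated Ks, excluded from mean_ks


@dataclass
class KaKsTable:
    """All inter-clade pairwise results plus per clade-pair averages.

    Ka is averaged over all defined pairs; Ks only over non-saturated
    ones (saturated pairs are counted, not capped).
    """

    pairs: dict[tuple[str, str], KaKsResult]
    pair_codes: dict[tuple[str, str], str]
    clade_pair_means: dict[str, CladePairStats] = field(default_factory=dict)

    def compute_means(self) -> None:
        for code in PAIR_CODES:
            results = [r for (p, r) in self.pairs.items() if self.pair_codes[p] == code]
            if not results:
                continue
            kas = [r.ka for r in results if not r.ka_saturated]
            kss = [r.ks for r in results if not r.ks_saturated]
            self.clade_pair_means[code] = CladePairStats(
                mean_ka=float(np.mean(kas)) if kas else float("nan"),
                mean_ks=float(np.mean(kss)) if kss else float("nan"),
                n_pairs=len(results),
                n_saturated=sum(r.ks_saturated for r in results),
            )

    def to_frame(self, gene: str = "") -> pd.DataFrame:
        rows = []
        for code, stats in self.clade_pair_means.items():
            rows.append(
                {
                    "gene": gene,
                    "clade_pair": code,
                    "mean_Ka": stats.mean_ka,
                    "mean_Ks": stats.mean_ks,
                    "n_pairs": stats.n_pairs,
                    "n_saturated": stats.n_saturated,
                }
            )
        return pd.DataFrame(rows)


def clade_average(codon_aln: CodonAlignment, clade_map: CladeMap) -> KaKsTable:
    """All-against-all inter-clade NG86 with per clade-pair averaging.

    Within-clade pairs are not computed. All three clades must be
    represented among the alignment rows.
    """
    clade_map.require_three_clades(codon_aln.ids)
    ids, enc = _encode_codons(codon_aln)
    row_of = {sid: i for i, sid in enumerate(ids)}
    pairs: dict[tuple[str, str], KaKsResult] = {}
    codes: dict[tuple[str, str], str] = {}
    for code, (ia, ib) in PAIR_CODES.items():
        clade_a = clade_map.clade_order[ia]
        clade_b = clade_map.clade_order[ib]
        for sa in (i for i in ids if clade_map.entries.get(i) == clade_a):
            for sb in (i for i in ids if clade_map.entries.get(i) == clade_b):
                res = _kaks_from_encoded(enc[row_of[sa]], enc[row_of[sb]])
                pairs[(sa, sb)] = res
                codes[(sa, sb)] = code
    table = KaKsTable(pairs=pairs, pair_codes=codes)
    table.compute_means()
    return table


@dataclass(frozen=True)
class KaKsCall:
    """Clade-average Ka contrast between metazoan and autotroph pairs."""

    metazoan_elevated: bool
    ka_gt_one: bool
    mean_ka: dict[str, float]


def kaks_contrast(table: KaKsTable) -> KaKsCall:
    """Is non-synonymous divergence elevated for metazoan comparisons?

    metazoan-elevated iff mean Ka(mf) > mean Ka(fp) AND
    mean Ka(mp) > mean Ka(fp) (strict). ka_gt_one reports whether both
    metazoan comparisons additionally exceed Ka = 1.
    """
    means = {c: s.mean_ka for c, s in table.clade_pair_means.items()}
    missing = [c for c in PAIR_CODES if c not in means]
    if missing:
        raise ValueError(f"clade pair(s) missing from table: {missing}")
    elevated = means["mf"] > means["fp"] and means["mp"] > means["fp"]
    gt_one = means["mf"] > 1.0 and means["mp"] > 1.0
    return KaKsCall(metazoan_elevated=bool(elevated), ka_gt_one=bool(gt_one), mean_ka=means)


def bootstrap_ka_contrast(
    codon_aln: CodonAlignment,
    clade_map: CladeMap,
    n_reps: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Nonparametric bootstrap CI for mean Ka(mf) - mean Ka(fp).

    Codon columns are resampled with replacement; for each replicate the
    clade-pair mean Ka values are recomputed (saturated pairs dropped)
    and the mf - fp difference recorded. Returns the point estimate, the
    2.5% / 97.5% percentiles, and the fraction of replicates > 0.
    """
    t = _tables()
    ids, enc = _encode_codons(codon_aln)
    row_of = {sid: i for i, sid in enumerate(ids)}
    # per clade-pair stacked per-codon contribution arrays
    group_arrays: dict[str, tuple[np.ndarray, ...]] = {}
    for code in ("mf", "fp"):
        ia, ib = PAIR_CODES[code]
        ids_a = [i for i in ids if clade_map.entries.get(i) == clade_map.clade_order[ia]]
        ids_b = [i for i in ids if clade_map.entries.get(i) == clade_map.clade_order[ib]]
        ss_l, ns_l, nd_l, valid_l = [], [], [], []
        for sa in ids_a:
            for sb in ids_b:
                a, b = enc[row_of[sa]], enc[row_of[sb]]
                valid = (a >= 0) & (b >= 0)
                av = np.where(valid, a, 0)
                bv = np.where(valid, b, 0)
                ss_l.append(np.where(valid, 0.5 * (t["syn_sites"][av] + t["syn_sites"][bv]), 0.0))
                ns_l.append(np.where(valid, 0.5 * (t["nonsyn_sites"][av] + t["nonsyn_sites"][bv]), 0.0))
                nd_l.append(np.where(valid, t["nonsyn_diffs"][av, bv], 0.0))
                valid_l.append(valid)
        group_arrays[code] = (
            np.asarray(ss_l),
            np.asarray(ns_l),
            np.asarray(nd_l),
            np.asarray(valid_l),
        )

    rng = np.random.default_rng(seed)
    n_codons = enc.shape[1]

    def mean_ka(code: str, cols: np.ndarray) -> float:
        _, ns, nd, _ = group_arrays[code]
        ns_sum = ns[:, cols].sum(axis=1)
        nd_sum = nd[:, cols].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            p_n = np.where(ns_sum > 0, nd_sum / ns_sum, 0.0)
            arg = 1.0 - (4.0 / 3.0) * p_n
            ka = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), np.nan)
        return float(np.nanmean(ka)) if np.isfinite(ka).any() else float("nan")

    full = np.arange(n_codons)
    point = mean_ka("mf", full) - mean_ka("fp", full)
    diffs = np.empty(n_reps)
    for r in range(n_reps):
        cols = rng.integers(0, n_codons, size=n_codons)
        diffs[r] = mean_ka("mf", cols) - mean_ka("fp", cols)
    return {
        "point": point,
        "ci_low": float(np.nanpercentile(diffs, 2.5)),
        "ci_high": float(np.nanpercentile(diffs, 97.5)),
        "frac_positive": float(np.nanmean(diffs > 0)),
        "n_reps": n_reps,
    }
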