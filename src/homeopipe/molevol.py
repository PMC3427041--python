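"""Pairwise molecular-evolution statistics for coding alignments.

The divergence machinery is the Nei–Gojobori (1986) counting method:
synonymous/nonsynonymous site counts from the fraction of single-base
changes per codon position that preserve the amino acid, observed
differences from equal-weight averaging over all orderings of single-step
mutational pathways in multi-difference codons, and Jukes–Cantor correction
d = -(3/4)·ln(1 - (4/3)p) for multiple hits. Alignments shorter than 198 bp
after ambiguous-codon removal are rejected, matching the filtering regime
the surrounding pipeline applies.

Lineage-specific substitutions are obtained by phylogenetic polarization of
four-taxon columns (diploid A, tetraploid A-homoeolog, diploid D, tetraploid
D-homoeolog): a column is attributed to a lineage only when that lineage
differs and the remaining three states are unanimous. Two tests round out
the module: a two-sided exact binomial comparison of substitution counts and
a Wilcoxon signed-rank test for paired per-contig dN/dS ratios.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._codon import CODON_TO_AA, codon_syn_sites

MIN_ALIGNMENT_BP = 198

LINEAGES = ("A2", "AT", "D5", "DT")


@dataclass
class CodonAlignment:
    """A paired in-frame coding alignment after filtering: gap-free,
    unambiguous codon pairs only."""

    contig_id: str
    pair: tuple
    codons: list  # [(codon_x, codon_y), ...]

    @property
    def n_sites(self) -> int:
        return 3 * len(self.codons)


@dataclass
class SubstEstimates:
    """NG86 counts and JC-corrected distances for one alignment."""

    Sd: float
    Nd: float
    S: float
    N: float

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else float("nan")

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else float("nan")

    @property
    def dS(self) -> float:
        return jc_correct(self.pS) if self.pS < 0.75 else float("nan")

    @property
    def dN(self) -> float:
        return jc_correct(self.pN) if self.pN < 0.75 else float("nan")

    @property
    def ratio(self) -> float:
        """dN/dS, defined only when dS > 0."""
        ds = self.dS
        if not (ds > 0):
            return float("nan")
        return self.dN / ds


@dataclass
class LineageCounts:
    """Polarized lineage-specific substitution counts over quartet columns."""

    counts: dict = field(default_factory=lambda: {k: 0 for k in LINEAGES})
    n_nucleotides: int = 0
    n_contigs: int = 0

    def __add__(self, other: "LineageCounts") -> "LineageCounts":
        return LineageCounts(
            {k: self.counts[k] + other.counts[k] for k in LINEAGES},
            self.n_nucleotides + other.n_nucleotides,
            self.n_contigs + other.n_contigs,
        )


# ---------------------------------------------------------------------------
# alignment extraction
# ---------------------------------------------------------------------------

def _bases_of(obj) -> str:
    return obj if isinstance(obj, str) else obj.bases


def extract_codon_alignment(
    cons_x,
    cons_y,
    frame: int = 0,
    min_len: int = MIN_ALIGNMENT_BP,
    contig_id: str = "",
    pair: tuple = ("X", "Y"),
) -> CodonAlignment | None:
    """In-frame overlap of two consensuses (or raw sequences), with every
    codon containing a masked or ambiguous base removed. Returns None when
    fewer than `min_len` nucleotides survive the filter."""
    x, y = _bases_of(cons_x), _bases_of(cons_y)
    n = min(len(x), len(y))
    offset = frame % 3
    codons = []
    for i in range(offset, n - 2, 3):
        cx, cy = x[i : i + 3], y[i : i + 3]
        if any(b not in "ACGT" for b in cx + cy):
            continue
        codons.append((cx, cy))
    ca = CodonAlignment(contig_id, pair, codons)
    if ca.n_sites < min_len:
        return None
    return ca


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def jc_correct(p: float) -> float:
    """Jukes-Cantor multiple-hit correction: -(3/4)·ln(1 - (4/3)p)."""
    if not 0.0 <= p < 0.75:
        raise ValueError(f"proportion {p} outside the JC domain [0, 0.75)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def _codon_pair_diffs(cx: str, cy: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair: equal-weight average over all orderings
    of the single-step mutational pathways from cx to cy. Orderings passing
    through a stop codon are excluded (all orderings are kept when every one
    is blocked, so the estimate stays defined)."""
    diff_pos = [i for i in range(3) if cx[i] != cy[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: tuple) -> tuple[float, float] | None:
        cur = cx
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + cy[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*" and nxt != cy:
                return None
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    orders = list(itertools.permutations(diff_pos))
    results = [walk(o) for o in orders]
    kept = [r for r in results if r is not None]
    if not kept:  # every pathway blocked by a stop: fall back to all
        kept = []
        for o in orders:
            cur = cx
            sd = nd = 0.0
            for pos in o:
                nxt = cur[:pos] + cy[pos] + cur[pos + 1 :]
                if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            kept.append((sd, nd))
    sd = sum(r[0] for r in kept) / len(kept)
    nd = sum(r[1] for r in kept) / len(kept)
    return sd, nd


def ng86(ca: CodonAlignment) -> SubstEstimates:
    """Nei-Gojobori counts for one codon alignment.

    Site counts are averaged over the two sequences; differences use the
    pathway-averaging rule of :func:`_codon_pair_diffs`.
    """
    S = Sd = Nd = 0.0
    for cx, cy in ca.codons:
        S += 0.5 * (codon_syn_sites(cx) + codon_syn_sites(cy))
        d_s, d_n = _codon_pair_diffs(cx, cy)
        Sd += d_s
        Nd += d_n
    N = ca.n_sites - S
    return SubstEstimates(Sd=Sd, Nd=Nd, S=S, N=N)


def pooled_ng86(alignments: Iterable[CodonAlignment]) -> SubstEstimates:
    """Aggregate NG86 counts over many alignments (sums, then proportions)."""
    total = SubstEstimates(0.0, 0.0, 0.0, 0.0)
    for ca in alignments:
        est = ng86(ca)
        total = SubstEstimates(
            total.Sd + est.Sd, total.Nd + est.Nd, total.S + est.S, total.N + est.N
        )
    return total


# ---------------------------------------------------------------------------
# per-contig survey
# ---------------------------------------------------------------------------

def pairwise_survey(
    sequences: Mapping[str, tuple],
    frames: Mapping[str, int] | None = None,
    pair: tuple = ("X", "Y"),
    min_len: int = MIN_ALIGNMENT_BP,
    exclude: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict]:
    """Per-contig NG86/JC estimates plus unweighted summary statistics.

    `sequences` maps contig id -> (consensus X, consensus Y); contigs in
    `exclude` (e.g. those carrying a detected NRHR event) are dropped before
    alignment extraction, as are contigs failing the length filter.
    Ratio summaries exclude contigs whose dS is zero or undefined.
    """
    excluded = set(exclude)
    rows = []
    for cid in sorted(sequences):
        if cid in excluded:
            continue
        frame = frames.get(cid, 0) if frames else 0
        ca = extract_codon_alignment(
            *sequences[cid], frame=frame, min_len=min_len, contig_id=cid, pair=pair
        )
        if ca is None:
            continue
        est = ng86(ca)
        rows.append(
            {
                "contig": cid,
                "pair": f"{pair[0]}:{pair[1]}",
                "n_sites": ca.n_sites,
                "Sd": est.Sd,
                "Nd": est.Nd,
                "S": est.S,
                "N": est.N,
                "dS": est.dS,
                "dN": est.dN,
                "ratio": est.ratio,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["contig", "pair", "n_sites", "Sd", "Nd", "S", "N", "dS", "dN", "ratio"],
    )
    ratios = table["ratio"].dropna() if len(table) else pd.Series(dtype=float)
    summary = {
        "n_contigs": len(table),
        "total_sites": int(table["n_sites"].sum()) if len(table) else 0,
        "mean_dS": float(table["dS"].mean()) if len(table) else float("nan"),
        "sd_dS": float(table["dS"].std()) if len(table) else float("nan"),
        "mean_dN": float(table["dN"].mean()) if len(table) else float("nan"),
        "sd_dN": float(table["dN"].std()) if len(table) else float("nan"),
        "mean_ratio": float(ratios.mean()) if len(ratios) else float("nan"),
        "sd_ratio": float(ratios.std()) if len(ratios) else float("nan"),
        "n_ratio": int(len(ratios)),
    }
    return table, summary


# ---------------------------------------------------------------------------
# lineage polarization
# ---------------------------------------------------------------------------

def polarize_substitutions(
    a2: str, a_t: str, d5: str, d_t: str
) -> LineageCounts:
    """Count lineage-specific substitutions over one quartet alignment.

    Only columns where all four states are unambiguous bases are counted
    toward n_nucleotides. A column increments a lineage's count iff that
    lineage's base differs from the other three and those three are
    identical; columns with two or more derived states are discarded.
    """
    n = min(len(a2), len(a_t), len(d5), len(d_t))
    arr = np.array(
        [list(a2[:n]), list(a_t[:n]), list(d5[:n]), list(d_t[:n])], dtype="<U1"
    )
    valid = np.ones(n, dtype=bool)
    for row in arr:
        valid &= np.isin(row, list("ACGT"))
    arr = arr[:, valid]
    lc = LineageCounts(n_nucleotides=int(arr.shape[1]), n_contigs=1)
    for i, name in enumerate(LINEAGES):
        others = np.delete(arr, i, axis=0)
        unanimous = (others[0] == others[1]) & (others[1] == others[2])
        lc.counts[name] = int(np.sum(unanimous & (arr[i] != others[0])))
    return lc


def pooled_lineage_counts(
    quartets: Iterable[tuple],
) -> LineageCounts:
    """Sum :func:`polarize_substitutions` over (a2, a_t, d5, d_t) quartets."""
    total = LineageCounts()
    for a2, a_t, d5, d_t in quartets:
        total = total + polarize_substitutions(a2, a_t, d5, d_t)
    return total


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def exact_binomial(k_tetra: int, k_diploid: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p-value for k_tetra successes in
    k_tetra + k_diploid trials at null proportion p0, two-sided by doubling
    the smaller tail (capped at 1)."""
    if k_tetra < 0 or k_diploid < 0 or k_tetra + k_diploid == 0:
        raise ValueError("counts must be non-negative with a positive total")
    n = k_tetra + k_diploid
    lower = stats.binom.cdf(k_tetra, n, p0)
    upper = stats.binom.sf(k_tetra - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


class WilcoxonResult(NamedTuple):
    statistic: float
    pvalue: float
    n_used: int


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float] | None = None
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; tied absolute differences are mid-ranked.
    The null distribution is exact for n <= 25 without ties, otherwise the
    normal approximation with continuity correction is used. Identical
    vectors give p = 1; fewer than 6 non-zero differences is an error.
    """
    x = np.asarray(x, dtype=float)
    if y is not None:
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired vectors must have equal length")
        d = x - y
    else:
        d = x
    d = d[~np.isnan(d)]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 1.0, 0)
    if n < 6:
        raise ValueError(f"only {n} non-zero differences; need at least 6")
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return WilcoxonResult(float(res.statistic), float(res.pvalue), n)
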