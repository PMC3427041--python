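"""Dataset accounting: species-membership Venn, assembly statistics,
coding-coverage and validation error-rate arithmetic."""
from __future__ import annotations

from collections import Counter
from itertools import chain, combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contigspace import ContigAlignment, DEFAULT_SPECIES


def species_venn(
    memberships: Mapping[str, Iterable[str]],
    species: Sequence[str] = DEFAULT_SPECIES,
) -> dict:
    """Counts per non-empty species subset (15 cells for four species).

    `memberships` maps contig id -> species with at least one read in that
    contig. Cells are disjoint and sum to the number of contigs.
    """
    cells: dict[frozenset, int] = {
        frozenset(c): 0
        for r in range(1, len(species) + 1)
        for c in combinations(species, r)
    }
    for cid, present in memberships.items():
        key = frozenset(present)
        if not key:
            raise ValueError(f"contig {cid} has an empty species set")
        unknown = key - set(species)
        if unknown:
            raise ValueError(f"contig {cid}: unknown species {sorted(unknown)}")
        cells[key] += 1
    return cells


def memberships_from_alignments(
    alignments: Mapping[str, ContigAlignment],
) -> dict:
    return {
        cid: {r.species for r in aln.reads}
        for cid, aln in alignments.items()
        if aln.reads
    }


def coding_coverage(
    mean_coding_len: float, reference_lens: Sequence[float]
) -> float:
    """Percent of the expected coding length covered by the assembly:
    100 x mean observed coding length / mean of the reference lengths."""
    if len(reference_lens) == 0:
        raise ValueError("reference length list is empty")
    ref_mean = float(np.mean(reference_lens))
    if ref_mean == 0:
        raise ValueError("reference mean length is zero")
    return 100.0 * mean_coding_len / ref_mean


def validation_error_rate(n_nucleotides: int, n_substitutions: int) -> float:
    """Percent substitution rate against independently sequenced references."""
    if n_nucleotides <= 0:
        raise ValueError("nucleotide count must be positive")
    return 100.0 * n_substitutions / n_nucleotides


def _lower_median(values: Sequence[float]) -> float:
    """Median taking the lower of the middle pair for even counts."""
    s = sorted(values)
    if not s:
        return float("nan")
    return s[(len(s) - 1) // 2]


def assembly_stats(alignments: Mapping[str, ContigAlignment]) -> dict:
    """Contig-level summaries: length distribution, reads per contig, and
    mean per-base depth over all contigs."""
    lengths = [aln.length for aln in alignments.values()]
    reads_per = [len(aln.reads) for aln in alignments.values()]
    total_read_bases = sum(
        len(r.bases) for aln in alignments.values() for r in aln.reads
    )
    total_len = sum(lengths)
    return {
        "n_contigs": len(alignments),
        "mean_length": float(np.mean(lengths)) if lengths else float("nan"),
        "min_length": min(lengths) if lengths else 0,
        "max_length": max(lengths) if lengths else 0,
        "median_reads_per_contig": _lower_median(reads_per),
        "mean_depth": total_read_bases / total_len if total_len else float("nan"),
    }


def format_percent(value: float) -> str:
    """One-decimal display rounding used in human-readable summaries."""
    return f"{value:.1f}%"


def venn_table(cells: Mapping[frozenset, int]) -> list:
    """Stable, sorted (subset, count) rows for TSV/JSON export."""
    rows = []
    for key in sorted(cells, key=lambda k: (len(k), tuple(sorted(k)))):
        rows.append(("+".join(sorted(key)), cells[key]))
    return rows
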