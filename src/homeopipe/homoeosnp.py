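"""Genome-diagnostic SNP calling for allopolyploid transcriptome alignments.

Two complementary callers mirror the two sequencing strategies of the study
design this package models:

* the *assembly* caller works on long-read contigs: majority-rule consensuses
  are built per diploid genome, candidate diagnostic columns are the unmasked
  differing positions, tetraploid reads are partitioned to subgenomes by
  voting at those columns, and a SNP is emitted only where the tetraploid
  A- and D-consensuses also differ and match the diploid alleles;
* the *pileup* caller works on deep short-read columns with per-call
  phred-scaled qualities from a posterior over column states (four fixed
  bases plus six balanced mixtures), requiring quality >= 20 by default.

Cross-platform reconciliation and confirmation of both parental alleles
inside the allotetraploids complete the module.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from ._codon import BASES, BASE_INDEX
from .contigspace import (
    AlignedRead,
    ContigAlignment,
    DIPLOID_A,
    DIPLOID_D,
    TETRAPLOIDS,
)

logger = logging.getLogger(__name__)

MASK = "N"


@dataclass
class Consensus:
    """Majority-rule consensus for one read group over one contig.

    Masked columns (tie, sub-threshold major-allele frequency, or depth
    below the minimum) carry the mask symbol 'N'.
    """

    contig_id: str
    group: str
    bases: str
    depth: np.ndarray
    major_freq: np.ndarray

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class DiagnosticSNP:
    """A genome-diagnostic site: fixed A-genome vs fixed D-genome allele."""

    contig_id: str
    pos: int  # 0-based
    a_allele: str
    d_allele: str
    platforms: set = field(default_factory=set)
    agreement: str = "single-platform"  # agree | disagree | single-platform
    confirmed: bool | None = None
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.a_allele == self.d_allele:
            raise ValueError(
                f"{self.contig_id}:{self.pos}: alleles must differ "
                f"({self.a_allele!r})"
            )

    @property
    def key(self) -> tuple:
        return (self.contig_id, self.pos)


@dataclass
class ReadAssignment:
    """Subgenome call for one tetraploid read from diagnostic-site votes."""

    read_id: str
    genome_call: str  # A | D | chimeric | unassigned
    sites_seen: int
    votes_A: int
    votes_D: int


@dataclass
class PlatformReconciliation:
    n_long: int
    n_short: int
    n_common: int
    n_agree: int
    n_disagree: int

    @property
    def n_union(self) -> int:
        """Inclusion-exclusion union of the two platform SNP sets."""
        return self.n_long + self.n_short - self.n_common

    @classmethod
    def from_counts(
        cls, n_long: int, n_short: int, n_common: int, n_disagree: int = 0
    ) -> "PlatformReconciliation":
        return cls(n_long, n_short, n_common, n_common - n_disagree, n_disagree)


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def consensus_from_matrix(
    mat: np.ndarray,
    contig_id: str,
    group: str,
    min_major_freq: float = 0.90,
    min_depth: int = 2,
) -> Consensus:
    """Column-wise majority rule over an (L, 4) count matrix.

    A column is masked when depth < min_depth, when the major allele is tied,
    or when its frequency is not strictly greater than min_major_freq.
    """
    depth = mat.sum(axis=1)
    major_idx = mat.argmax(axis=1)
    major_count = mat.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(depth > 0, major_count / np.maximum(depth, 1), 0.0)
    tie = (mat == major_count[:, None]).sum(axis=1) > 1
    ok = (depth >= min_depth) & ~tie & (freq > min_major_freq)
    chars = np.full(mat.shape[0], MASK, dtype="<U1")
    base_arr = np.array(list(BASES))
    chars[ok] = base_arr[major_idx[ok]]
    return Consensus(contig_id, group, "".join(chars), depth, freq)


def consensus_from_reads(
    reads: Iterable[AlignedRead],
    length: int,
    contig_id: str,
    group: str,
    min_major_freq: float = 0.90,
    min_depth: int = 2,
) -> Consensus:
    mat = np.zeros((length, 4), dtype=np.int32)
    for r in reads:
        enc = r.encoded()
        valid = enc >= 0
        pos = np.arange(r.start, r.end)[valid]
        np.add.at(mat, (pos, enc[valid].astype(np.intp)), 1)
    return consensus_from_matrix(mat, contig_id, group, min_major_freq, min_depth)


def build_consensus(
    aln: ContigAlignment,
    group: str | Sequence[str],
    min_major_freq: float = 0.90,
    min_depth: int = 2,
    platform: str | None = None,
) -> Consensus:
    """Majority-rule consensus for one species (or species set) in a contig."""
    known = {r.species for r in aln.reads}
    wanted = {group} if isinstance(group, str) else set(group)
    if not wanted & known and aln.reads:
        raise KeyError(f"group {group!r} absent from contig {aln.contig_id}")
    mat = aln.count_matrix(group, platform)
    name = group if isinstance(group, str) else "+".join(sorted(group))
    return consensus_from_matrix(mat, aln.contig_id, name, min_major_freq, min_depth)


# ---------------------------------------------------------------------------
# assembly (long-read) calling
# ---------------------------------------------------------------------------

def diploid_diagnostic_sites(
    aln: ContigAlignment,
    min_major_freq: float = 0.90,
    min_depth: int = 2,
    platform: str | None = "long",
) -> list[DiagnosticSNP]:
    """Candidate diagnostic sites: unmasked columns where the two diploid
    consensuses differ. This is the site set used for read partitioning and
    NRHR detection (no tetraploid filter is applied here)."""
    species = {r.species for r in aln.reads}
    if DIPLOID_A not in species or DIPLOID_D not in species:
        logger.info(
            "contig %s skipped: missing diploid genome(s)", aln.contig_id
        )
        return []
    cons_a = build_consensus(aln, DIPLOID_A, min_major_freq, min_depth, platform)
    cons_d = build_consensus(aln, DIPLOID_D, min_major_freq, min_depth, platform)
    out = []
    for pos, (a, d) in enumerate(zip(cons_a.bases, cons_d.bases)):
        if a != d and a != MASK and d != MASK:
            out.append(DiagnosticSNP(aln.contig_id, pos, a, d, platforms={"long"}))
    return out


def assign_read(
    read: AlignedRead,
    snps: Sequence[DiagnosticSNP],
    min_qual: float | None = None,
) -> ReadAssignment:
    """Categorize a tetraploid read as A, D, chimeric or unassigned by its
    bases at the covered diagnostic sites. Bases matching neither parental
    allele are ignored for voting; optional `min_qual` drops low-quality
    bases from consideration."""
    votes_a = votes_d = sites_seen = 0
    for snp in snps:
        b = read.base_at(snp.pos)
        if b is None:
            continue
        sites_seen += 1
        if min_qual is not None:
            q = read.qual_at(snp.pos)
            if q is not None and q < min_qual:
                continue
        if b == snp.a_allele:
            votes_a += 1
        elif b == snp.d_allele:
            votes_d += 1
    if votes_a and votes_d:
        call = "chimeric"
    elif votes_a:
        call = "A"
    elif votes_d:
        call = "D"
    else:
        call = "unassigned"
    return ReadAssignment(read.read_id, call, sites_seen, votes_a, votes_d)


def call_assembly_snps(
    aln: ContigAlignment,
    min_major_freq: float = 0.90,
    min_depth: int = 2,
) -> list[DiagnosticSNP]:
    """Long-read pipeline: diploid consensuses -> candidate diagnostics ->
    tetraploid read partitioning -> tetraploid subgenome consensuses ->
    emit sites where the tetraploid consensuses differ and match the
    respective diploid alleles."""
    candidates = diploid_diagnostic_sites(aln, min_major_freq, min_depth, "long")
    if not candidates:
        return []
    # Candidate refinement: diploid-difference columns include diploid
    # lineage-specific mutations, which are not diagnostic — at such a site
    # every tetraploid read carries the ancestral (single) allele. A genuine
    # diagnostic site shows both parental alleles among the tetraploid reads
    # (one per homoeolog), so we require minimal support for each before
    # using a site for read partitioning.
    mat_tetra = aln.count_matrix(TETRAPLOIDS, "long")
    refined = [
        snp
        for snp in candidates
        if mat_tetra[snp.pos, BASE_INDEX[snp.a_allele]] >= min_depth
        and mat_tetra[snp.pos, BASE_INDEX[snp.d_allele]] >= min_depth
    ]
    # Pooling is by majority vote, not the strict chimeric classes: residual
    # non-diagnostic sites put stray opposite votes on reads, and the strict
    # classes would discard them wholesale. The tetraploid consensus stage
    # below still rejects any site whose alleles contradict the diploid pair.
    pools: dict[str, list[AlignedRead]] = {"A": [], "D": []}
    for read in aln.iter_reads(TETRAPLOIDS, platform="long"):
        asg = assign_read(read, refined)
        if asg.votes_A > asg.votes_D:
            pools["A"].append(read)
        elif asg.votes_D > asg.votes_A:
            pools["D"].append(read)
    cons_ta = consensus_from_reads(
        pools["A"], aln.length, aln.contig_id, "AT", min_major_freq, min_depth
    )
    cons_td = consensus_from_reads(
        pools["D"], aln.length, aln.contig_id, "DT", min_major_freq, min_depth
    )
    out = []
    for snp in refined:
        ta, td = cons_ta.bases[snp.pos], cons_td.bases[snp.pos]
        if ta == MASK or td == MASK or ta == td:
            continue
        if ta == snp.a_allele and td == snp.d_allele:
            out.append(snp)
    return out


# ---------------------------------------------------------------------------
# pileup (short-read) calling
# ---------------------------------------------------------------------------

_PAIRS = [(i, j) for i in range(4) for j in range(i + 1, 4)]


def column_state_posterior(
    counts: np.ndarray, err: float = 1e-2
) -> tuple[str | None, float]:
    """Posterior over column states given ACGT counts under a per-base error
    model (correct with probability 1-err, otherwise uniform on the other
    bases). States are the four fixed bases plus the six balanced two-allele
    mixtures, with a uniform prior; the mixture states guard against calling
    a fixed consensus from a column that may be polymorphic within the group.

    Returns (consensus base or None, phred-scaled quality), where quality is
    -10*log10 P(consensus wrong | counts). None means no fixed state wins.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return None, 0.0
    p_hit, p_miss = np.log(1.0 - err), np.log(err / 3.0)
    logls = []
    for b in range(4):
        per_base = np.full(4, p_miss)
        per_base[b] = p_hit
        logls.append(float(counts @ per_base))
    for i, j in _PAIRS:
        per_base = np.full(4, np.exp(p_miss))
        per_base[i] = per_base[j] = 0.5 * (np.exp(p_hit) + np.exp(p_miss))
        logls.append(float(counts @ np.log(per_base)))
    logls = np.array(logls)
    total = logsumexp(logls)
    best = int(np.argmax(logls))
    if best >= 4:
        return None, 0.0
    others = np.delete(logls, best)
    p_wrong = np.exp(logsumexp(others) - total)
    qual = 99.0 if p_wrong <= 0 else min(99.0, -10.0 * np.log10(p_wrong))
    return BASES[best], float(qual)


def call_pileup_snps(
    aln: ContigAlignment,
    min_qual: float = 20.0,
    err: float = 1e-2,
) -> list[DiagnosticSNP]:
    """Short-read caller: per diploid group, the column consensus must be a
    fixed base with quality >= min_qual; a SNP is emitted where the A- and
    D-group consensuses differ."""
    species = {r.species for r in aln.reads}
    if DIPLOID_A not in species or DIPLOID_D not in species:
        return []
    mat_a = aln.count_matrix(DIPLOID_A, "short")
    mat_d = aln.count_matrix(DIPLOID_D, "short")
    out = []
    both = (mat_a.sum(axis=1) > 0) & (mat_d.sum(axis=1) > 0)
    for pos in np.flatnonzero(both):
        base_a, qual_a = column_state_posterior(mat_a[pos], err)
        if base_a is None or qual_a < min_qual:
            continue
        base_d, qual_d = column_state_posterior(mat_d[pos], err)
        if base_d is None or qual_d < min_qual or base_a == base_d:
            continue
        out.append(
            DiagnosticSNP(
                aln.contig_id,
                int(pos),
                base_a,
                base_d,
                platforms={"short"},
                qual=min(qual_a, qual_d),
            )
        )
    return out


# ---------------------------------------------------------------------------
# confirmation and reconciliation
# ---------------------------------------------------------------------------

def confirm_in_tetraploid(
    snp: DiagnosticSNP, aln: ContigAlignment, platform: str | None = "short"
) -> bool:
    """A SNP is confirmed when at least one allotetraploid read carries each
    parental allele at the site — the guard against diploid lineage-specific
    mutation and tetraploid homoeolog loss."""
    counts = aln.column_counts(snp.pos, TETRAPLOIDS, platform)
    confirmed = counts.get(snp.a_allele, 0) >= 1 and counts.get(snp.d_allele, 0) >= 1
    snp.confirmed = confirmed
    return confirmed


def reconcile_platforms(
    long_snps: Sequence[DiagnosticSNP], short_snps: Sequence[DiagnosticSNP]
) -> PlatformReconciliation:
    """Cross-platform accounting keyed by (contig, pos): shared keys are
    `common`; a common SNP agrees when both platforms report the same
    oriented allele pair. Disagreeing SNPs are flagged, not dropped."""
    by_key_long: dict[tuple, DiagnosticSNP] = {}
    for snp in long_snps:
        if snp.key in by_key_long:
            raise ValueError(f"duplicate long-platform SNP at {snp.key}")
        by_key_long[snp.key] = snp
    by_key_short: dict[tuple, DiagnosticSNP] = {}
    for snp in short_snps:
        if snp.key in by_key_short:
            raise ValueError(f"duplicate short-platform SNP at {snp.key}")
        by_key_short[snp.key] = snp

    common = set(by_key_long) & set(by_key_short)
    n_agree = 0
    for key in common:
        a, b = by_key_long[key], by_key_short[key]
        same = (a.a_allele, a.d_allele) == (b.a_allele, b.d_allele)
        a.agreement = b.agreement = "agree" if same else "disagree"
        a.platforms |= b.platforms
        b.platforms |= a.platforms
        n_agree += same
    return PlatformReconciliation(
        n_long=len(by_key_long),
        n_short=len(by_key_short),
        n_common=len(common),
        n_agree=n_agree,
        n_disagree=len(common) - n_agree,
    )


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_snps_tsv(snps: Sequence[DiagnosticSNP], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tpos\ta_allele\td_allele\tplatforms\tagreement\tconfirmed\tqual\n")
        for s in sorted(snps, key=lambda s: s.key):
            conf = "." if s.confirmed is None else ("yes" if s.confirmed else "no")
            qual = "." if s.qual is None else f"{s.qual:.1f}"
            fh.write(
                f"{s.contig_id}\t{s.pos}\t{s.a_allele}\t{s.d_allele}\t"
                f"{','.join(sorted(s.platforms))}\t{s.agreement}\t{conf}\t{qual}\n"
            )


def load_snps_tsv(path: str | Path) -> list[DiagnosticSNP]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            cid, pos, a, d, plats, agree, conf, qual = line.rstrip("\n").split("\t")
            out.append(
                DiagnosticSNP(
                    cid,
                    int(pos),
                    a,
                    d,
                    platforms=set(plats.split(",")) if plats else set(),
                    agreement=agree,
                    confirmed=None if conf == "." else conf == "yes",
                    qual=None if qual == "." else float(qual),
                )
            )
    return out


def write_snps_vcf(
    snps: Sequence[DiagnosticSNP],
    contig_lengths: Mapping[str, int],
    path: str | Path,
) -> None:
    """Minimal VCF export: 1-based POS, REF = A-genome allele, ALT = D-genome
    allele, INFO fields PLAT/CONF/AGREE."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PLAT,Number=.,Type=String,Description="Platforms">\n')
        fh.write('##INFO=<ID=CONF,Number=1,Type=String,Description="Confirmed in tetraploids">\n')
        fh.write('##INFO=<ID=AGREE,Number=1,Type=String,Description="Cross-platform agreement">\n')
        for cid in sorted(contig_lengths):
            fh.write(f"##contig=<ID={cid},length={contig_lengths[cid]}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda s: s.key):
            qual = "." if s.qual is None else f"{s.qual:.1f}"
            conf = "." if s.confirmed is None else ("yes" if s.confirmed else "no")
            info = f"PLAT={','.join(sorted(s.platforms))};CONF={conf};AGREE={s.agreement}"
            fh.write(
                f"{s.contig_id}\t{s.pos + 1}\t.\t{s.a_allele}\t{s.d_allele}\t"
                f"{qual}\tPASS\t{info}\n"
            )
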