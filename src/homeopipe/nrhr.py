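"""Detection of nonreciprocal homoeologous recombination (NRHR).

A conversion tract transfers a run of one subgenome's diagnostic alleles onto
the other homoeolog. In read space this shows up as *chimeric* allotetraploid
reads carrying both A- and D-genome diagnostic alleles. Detection proceeds
per contig and per tetraploid species:

1. scan tetraploid reads over the diagnostic-site list and keep those whose
   high-quality bases match both an A and a D parental allele;
2. bin reads into unique events: reads belong to one event when they share or
   extend a continuous diagnostic-allele haplotype (connected components of
   the pairwise agree-and-overlap graph);
3. match events across the two tetraploid species — identical states at every
   shared diagnostic site means the exchange was most parsimoniously present
   in their common ancestor ("shared"); otherwise it is species-specific
   (parallel mutation cannot be excluded and is reported as a caveat flag on
   shared events, not resolved).

A genome-wide rate corrected by an external validation rate closes the
module.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .contigspace import AlignedRead, ContigAlignment, TETRAPLOIDS
from .homoeosnp import DiagnosticSNP


@dataclass
class SnpStateVector:
    """Per-read states over the diagnostic sites it covers with a parental
    allele: 'A' for the A-genome allele, 'D' for the D-genome allele."""

    read_id: str
    species: str
    states: tuple  # ((site_index, 'A'|'D'), ...) with strictly increasing indices

    def as_dict(self) -> dict:
        return dict(self.states)

    @property
    def is_chimeric(self) -> bool:
        vals = {s for _, s in self.states}
        return "A" in vals and "D" in vals


@dataclass
class NRHREvent:
    """A maximal set of mutually compatible chimeric reads supporting one
    homoeologous-exchange haplotype."""

    contig_id: str
    event_id: str
    haplotype: dict  # site_index -> 'A' | 'D'
    n_switches: int
    supporting_reads: dict  # species -> read count
    read_ids: list
    placement: str | None = None  # species label | "shared" | None
    bp_span: tuple | None = None  # (start, end] in contig coordinates
    conflict: bool = False  # within-event disagreement resolved by majority
    parallel_mutation_possible: bool = False  # set on shared placements

    @property
    def sites(self) -> tuple:
        return tuple(sorted(self.haplotype))

    @property
    def n_support(self) -> int:
        return sum(self.supporting_reads.values())


# ---------------------------------------------------------------------------
# chimeric read discovery
# ---------------------------------------------------------------------------

def read_state_vector(
    read: AlignedRead,
    snps: Sequence[DiagnosticSNP],
    min_qual: float | None = 20.0,
) -> SnpStateVector:
    """States of one read over the diagnostic sites it covers. Bases matching
    neither parental allele yield no state; bases below `min_qual` (when
    qualities are present) are dropped as a sequencing-error guard."""
    states = []
    for idx, snp in enumerate(snps):
        b = read.base_at(snp.pos)
        if b is None:
            continue
        if min_qual is not None:
            q = read.qual_at(snp.pos)
            if q is not None and q < min_qual:
                continue
        if b == snp.a_allele:
            states.append((idx, "A"))
        elif b == snp.d_allele:
            states.append((idx, "D"))
    return SnpStateVector(read.read_id, read.species, tuple(states))


def find_chimeric_reads(
    aln: ContigAlignment,
    snps: Sequence[DiagnosticSNP],
    min_qual: float | None = 20.0,
    species: str | Sequence[str] = TETRAPLOIDS,
    platform: str | None = "long",
) -> list[SnpStateVector]:
    """Tetraploid reads whose diagnostic states include both genomes."""
    positions = [s.pos for s in snps]
    if any(b > a for a, b in zip(positions[1:], positions)):
        raise ValueError("diagnostic SNPs must be sorted by position")
    out = []
    for read in aln.iter_reads(species, platform):
        vec = read_state_vector(read, snps, min_qual)
        if vec.is_chimeric:
            out.append(vec)
    return out


# ---------------------------------------------------------------------------
# event binning
# ---------------------------------------------------------------------------

def _compatible(a: dict, b: dict) -> bool:
    """Reads share-or-extend one haplotype: >=1 shared site, no disagreement."""
    shared = a.keys() & b.keys()
    return bool(shared) and all(a[s] == b[s] for s in shared)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _haplotype_of(vecs: Sequence[SnpStateVector]) -> tuple[dict, bool]:
    """Union pattern of a read set; per-site majority on (rare) chain-induced
    disagreements, with a conflict flag. Sites with tied votes are dropped."""
    votes: dict[int, Counter] = {}
    for v in vecs:
        for site, state in v.states:
            votes.setdefault(site, Counter())[state] += 1
    hap: dict[int, str] = {}
    conflict = False
    for site, ctr in votes.items():
        if len(ctr) > 1:
            conflict = True
            (s1, c1), (s2, c2) = ctr.most_common(2)
            if c1 == c2:
                continue
            hap[site] = s1
        else:
            hap[site] = next(iter(ctr))
    return hap, conflict


def _count_switches(hap: Mapping[int, str]) -> int:
    ordered = [hap[s] for s in sorted(hap)]
    return sum(1 for x, y in zip(ordered, ordered[1:]) if x != y)


def bin_events(
    vectors: Sequence[SnpStateVector],
    snps: Sequence[DiagnosticSNP] | None = None,
    contig_id: str | None = None,
) -> list[NRHREvent]:
    """Bin chimeric reads of one contig into unique events.

    Reads merge when they overlap at >=1 diagnostic site and agree at every
    shared site, transitively (the share-or-extend closure). Each closure
    class whose merged haplotype retains at least one A/D switch is one
    event. The result is invariant under permutation of the input reads.
    """
    if not vectors:
        return []
    cid = contig_id or "contig"
    uf = _UnionFind(len(vectors))
    dicts = [v.as_dict() for v in vectors]
    for i in range(len(vectors)):
        for j in range(i + 1, len(vectors)):
            if _compatible(dicts[i], dicts[j]):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(vectors)):
        groups.setdefault(uf.find(i), []).append(i)

    events = []
    for members in sorted(groups.values(), key=lambda m: min(m)):
        vecs = [vectors[i] for i in members]
        hap, conflict = _haplotype_of(vecs)
        n_switches = _count_switches(hap)
        if n_switches < 1:
            continue
        support = Counter(v.species for v in vecs)
        sites = sorted(hap)
        span = None
        if snps is not None:
            span = (snps[sites[0]].pos, snps[sites[-1]].pos + 1)
        events.append(
            NRHREvent(
                contig_id=cid,
                event_id=f"{cid}:ev{len(events)}",
                haplotype=hap,
                n_switches=n_switches,
                supporting_reads=dict(support),
                read_ids=sorted(v.read_id for v in vecs),
                bp_span=span,
                conflict=conflict,
            )
        )
    return events


# ---------------------------------------------------------------------------
# phylogenetic placement
# ---------------------------------------------------------------------------

def _events_match(a: NRHREvent, b: NRHREvent) -> bool:
    shared = a.haplotype.keys() & b.haplotype.keys()
    return bool(shared) and all(a.haplotype[s] == b.haplotype[s] for s in shared)


def place_events(events_by_species: Mapping[str, Sequence[NRHREvent]]) -> list[NRHREvent]:
    """Match events called independently per tetraploid species on the same
    contig coordinates. Two events are the same (ancestral) exchange when
    they agree at every diagnostic site present in both; sites covered in
    only one species are ignored. Unmatched events are species-specific."""
    species = sorted(events_by_species)
    if not species:
        return []
    if len(species) == 1:
        out = []
        for ev in events_by_species[species[0]]:
            ev.placement = species[0]
            out.append(ev)
        return out
    sp1, sp2 = species[:2]
    placed: list[NRHREvent] = []
    taken: set[int] = set()
    for ev in events_by_species[sp1]:
        match = None
        for j, other in enumerate(events_by_species[sp2]):
            if j in taken:
                continue
            if ev.contig_id == other.contig_id and _events_match(ev, other):
                match = (j, other)
                break
        if match is None:
            ev.placement = sp1
            placed.append(ev)
            continue
        j, other = match
        taken.add(j)
        hap = dict(other.haplotype)
        hap.update(ev.haplotype)
        support = Counter(ev.supporting_reads) + Counter(other.supporting_reads)
        sites = sorted(hap)
        spans = [s for s in (ev.bp_span, other.bp_span) if s is not None]
        merged = NRHREvent(
            contig_id=ev.contig_id,
            event_id=ev.event_id,
            haplotype=hap,
            n_switches=_count_switches(hap),
            supporting_reads=dict(support),
            read_ids=sorted(ev.read_ids + other.read_ids),
            placement="shared",
            bp_span=(min(s[0] for s in spans), max(s[1] for s in spans)) if spans else None,
            conflict=ev.conflict or other.conflict,
            parallel_mutation_possible=True,
        )
        placed.append(merged)
    for j, other in enumerate(events_by_species[sp2]):
        if j not in taken:
            other.placement = sp2
            placed.append(other)
    return placed


# ---------------------------------------------------------------------------
# pipeline, summaries, rate estimate
# ---------------------------------------------------------------------------

def detect_nrhr(
    aln: ContigAlignment,
    snps: Sequence[DiagnosticSNP],
    min_qual: float | None = 20.0,
    min_support: int = 2,
    min_state_sites: int = 2,
    platform: str | None = "long",
) -> list[NRHREvent]:
    """Full per-contig pipeline: chimeric reads -> per-species binning ->
    cross-species placement -> support filters.

    Two guards sit on top of the raw binning. `min_support` (total reads per
    placed event) targets residual sequencing error: a single read cannot
    distinguish a conversion tract from a read-level artifact, while two
    independent reads sharing the haplotype make an error collision
    quadratically unlikely. `min_state_sites` requires each genome state at
    that many diagnostic sites, and one of the two states must occupy a
    single contiguous block of the haplotype: a conversion tract is an
    interval, so the introgressed state runs over consecutive sites (the
    flanking state may legitimately be split on both sides of the tract).
    A single opposite-genome site is indistinguishable from a point
    substitution arisen after polyploid formation (autapomorphic
    homoplasy), and two such scattered sites are not a tract.
    """
    vectors = find_chimeric_reads(aln, snps, min_qual, platform=platform)
    by_species: dict[str, list] = {}
    for v in vectors:
        by_species.setdefault(v.species, []).append(v)
    events_by_species = {
        sp: bin_events(vecs, snps, aln.contig_id) for sp, vecs in by_species.items()
    }
    placed = place_events(events_by_species)
    out = []
    for ev in placed:
        if ev.n_support < min_support:
            continue
        ordered = [ev.haplotype[s] for s in sorted(ev.haplotype)]
        counts = Counter(ordered)
        if min(counts.get("A", 0), counts.get("D", 0)) < min_state_sites:
            continue
        blocks = Counter(cur for prev, cur in zip([None] + ordered[:-1], ordered)
                         if cur != prev)
        if min(blocks["A"], blocks["D"]) > 1:  # neither state is one interval
            continue
        out.append(ev)
    return out


def summarize_contigs(events: Iterable[NRHREvent]) -> dict:
    """Event and contig accounting; multi-event contigs count once."""
    events = list(events)
    contigs = {ev.contig_id for ev in events}
    per_placement = Counter(ev.placement for ev in events)
    return {
        "n_events": len(events),
        "n_contigs_with_events": len(contigs),
        "per_placement": dict(per_placement),
    }


def estimate_true_rate(
    n_contigs_with_events: int,
    n_total_contigs: int,
    validation_rate: float = 0.70,
) -> float:
    """Validation-corrected fraction of contigs with a true exchange:
    validation_rate x affected / total."""
    if n_total_contigs <= 0:
        raise ValueError("total contig count must be positive")
    if n_contigs_with_events < 0:
        raise ValueError("affected contig count must be non-negative")
    return validation_rate * n_contigs_with_events / n_total_contigs


# ---------------------------------------------------------------------------
# truth-based evaluation (for simulated data)
# ---------------------------------------------------------------------------

def evaluate_detection(
    events: Sequence[NRHREvent],
    truths: Mapping[str, "object"],
    snps_by_contig: Mapping[str, Sequence[DiagnosticSNP]],
    min_inside_sites: int = 2,
    min_outside_sites: int = 1,
) -> dict:
    """Score detected events against planted tracts.

    A detected event matches a planted tract when, on the same contig, at
    least one haplotype site inside the tract carries the donor-genome state
    and at least one site outside carries the recipient-genome state.
    Placement accuracy is scored on matched events against the planted scope
    (species label or 'shared').

    Recall is computed over *detectable* tracts only: those covering at
    least `min_inside_sites` of the callable diagnostic sites actually
    available to the detector, with at least `min_outside_sites` outside —
    a tract whose diagnostic columns are all masked (e.g. low-depth contig
    edges) cannot, even in principle, produce a chimeric read. Precision
    counts every detected event.
    """
    truth_list = []
    for cid, truth in truths.items():
        positions = np.array(
            [s.pos for s in snps_by_contig.get(cid, [])], dtype=np.intp
        )
        for tr in truth.true_nrhr:
            inside = int(
                np.searchsorted(positions, tr.end) - np.searchsorted(positions, tr.start)
            )
            detectable = (
                inside >= min_inside_sites
                and positions.size - inside >= min_outside_sites
            )
            truth_list.append((cid, tr, detectable))

    def match(ev: NRHREvent, cid: str, tr) -> bool:
        if ev.contig_id != cid:
            return False
        snps = snps_by_contig.get(cid, [])
        donor = "A" if tr.recipient == "D" else "D"
        inside_donor = outside_recip = False
        for site, state in ev.haplotype.items():
            if site >= len(snps):
                continue
            pos = snps[site].pos
            if tr.start <= pos < tr.end and state == donor:
                inside_donor = True
            elif (pos < tr.start or pos >= tr.end) and state == tr.recipient:
                outside_recip = True
        return inside_donor and outside_recip

    matched_truths = set()
    matched_events = []
    for ev in events:
        hit = None
        for k, (cid, tr, _) in enumerate(truth_list):
            if match(ev, cid, tr):
                hit = k
                break
        if hit is not None:
            matched_truths.add(hit)
            matched_events.append((ev, truth_list[hit][1]))

    detectable_idx = {k for k, (_, _, det) in enumerate(truth_list) if det}
    n_det = len(events)
    recall = (
        len(matched_truths & detectable_idx) / len(detectable_idx)
        if detectable_idx
        else float("nan")
    )
    precision = len(matched_events) / n_det if n_det else float("nan")
    placement_ok = sum(1 for ev, tr in matched_events if ev.placement == tr.scope)
    placement_acc = (
        placement_ok / len(matched_events) if matched_events else float("nan")
    )
    return {
        "n_true": len(truth_list),
        "n_detectable": len(detectable_idx),
        "n_detected": n_det,
        "recall": recall,
        "precision": precision,
        "placement_accuracy": placement_acc,
    }


def write_events_tsv(events: Sequence[NRHREvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "contig\tevent_id\tsite_lo\tsite_hi\tbp_start\tbp_end\tn_switches\t"
            "placement\tsupport\tconflict\tparallel_mutation_possible\thaplotype\n"
        )
        for ev in sorted(events, key=lambda e: (e.contig_id, e.event_id)):
            sites = ev.sites
            bp = ev.bp_span or (-1, -1)
            support = ",".join(
                f"{sp}:{n}" for sp, n in sorted(ev.supporting_reads.items())
            )
            hap = ",".join(f"{s}{ev.haplotype[s]}" for s in sites)
            fh.write(
                f"{ev.contig_id}\t{ev.event_id}\t{sites[0]}\t{sites[-1] + 1}\t"
                f"{bp[0]}\t{bp[1]}\t{ev.n_switches}\t{ev.placement}\t{support}\t"
                f"{int(ev.conflict)}\t{int(ev.parallel_mutation_possible)}\t{hap}\n"
            )
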