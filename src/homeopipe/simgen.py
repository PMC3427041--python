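"""Synthetic allopolyploid transcriptome generator with full truth records.

The generator emulates the four-genome structure of the cotton system: two
model diploid progenitors (A2, D5) and the A- and D-homoeologs resident in two
allotetraploid species (AD1, AD2). Per contig it simulates, in order:

1. an ancestral in-frame coding sequence (random sense codons, no stops),
2. divergence of the A- and D-genome ancestors at a target synonymous
   distance (default dS ≈ 0.036) under a configurable dN/dS acceptance
   filter (default 0.3),
3. short post-polyploidization branches for A2, D5 and each species' A_T and
   D_T homoeologs (star phylogeny within each genome; A2 sister to A_T, D5
   sister to D_T),
4. optional nonreciprocal homoeologous recombination (NRHR) tracts that
   overwrite one homoeolog's tract with the other's, species-specific or
   shared (ancestral),
5. platform-specific shotgun reads (long ~250-450 bp, short 82 bp) with
   independent substitution errors and per-base qualities.

Everything is driven by one seeded ``numpy`` generator, so identical configs
produce byte-identical output files. Indels, expression levels and
homopolymer-specific error modes are deliberately not modelled; the
downstream analyses are substitution-based.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import yaml

from ._codon import BASES, CODON_TO_AA, SENSE_CODONS
from .contigspace import (
    AlignedRead,
    ContigAlignment,
    DIPLOID_A,
    DIPLOID_D,
    TETRAPLOIDS,
    load_alignment,
    write_placement_tsv,
)

# two-class per-base quality model: most bases are high quality, a minority
# are poor; the mixture weight is calibrated to the configured mean error
_GOOD_Q, _BAD_Q = 40, 12
_GOOD_E, _BAD_E = 10 ** (-_GOOD_Q / 10), 10 ** (-_BAD_Q / 10)


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults follow the cotton system: inter-genome synonymous divergence
    near 0.036 with dN/dS ≈ 0.3, short post-polyploid branches, ~7% of
    contigs carrying an NRHR tract of which ~23% are ancestral (shared by
    both allotetraploid species), long reads at 250–450 bp and short
    82 bp reads with base qualities.
    """

    n_contigs: int = 200
    contig_len_mean: float = 900.0
    contig_len_sd: float = 250.0
    min_contig_len: int = 300
    target_dS_AD: float = 0.036
    target_dnds: float = 0.3
    branch_dS: dict = field(
        default_factory=lambda: {"A2": 0.005, "AT": 0.006, "D5": 0.009, "DT": 0.010}
    )
    nrhr_contig_frac: float = 0.07
    nrhr_tract_len_mean: float = 150.0
    nrhr_shared_frac: float = 0.23
    long_read_len: tuple = (250, 450)
    long_cov: float = 20.0
    short_read_len: int = 82
    short_cov: float = 40.0
    long_err: float = 0.005
    short_err: float = 0.01
    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("nrhr_contig_frac", "nrhr_shared_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.target_dnds:
            raise ValueError("target_dnds must be >= 0")
        for name in ("target_dS_AD", "long_err", "short_err", "long_cov", "short_cov"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for v in self.branch_dS.values():
            if v < 0:
                raise ValueError("branch dS rates must be >= 0")
        if self.n_contigs < 0 or self.min_contig_len <= 0 or self.short_read_len <= 0:
            raise ValueError("counts and lengths must be positive")
        lo, hi = self.long_read_len
        if not (0 < lo <= hi):
            raise ValueError(f"invalid long_read_len range {self.long_read_len}")
        return self


@dataclass
class NRHRTract:
    """One planted conversion tract. `scope` is a species label or 'shared';
    `recipient` is the genome whose tract was overwritten ('A' or 'D')."""

    scope: str
    recipient: str
    start: int
    end: int


@dataclass
class SyntheticTruth:
    """Per-contig truth: lineage sequences, diagnostic sites, NRHR tracts."""

    contig_id: str
    frame: int
    ancestor: str
    a2: str
    d5: str
    a_t: dict  # species -> sequence
    d_t: dict
    true_snps: list = field(default_factory=list)  # (pos, a_allele, d_allele)
    true_nrhr: list = field(default_factory=list)  # NRHRTract

    @property
    def length(self) -> int:
        return len(self.ancestor)

    def snp_positions(self) -> np.ndarray:
        return np.array([p for p, _, _ in self.true_snps], dtype=np.intp)


@dataclass
class SimulatedDataset:
    config: SimConfig
    truths: dict  # contig_id -> SyntheticTruth
    alignments: dict  # contig_id -> ContigAlignment


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _p_from_d(d: float) -> float:
    """Invert the Jukes-Cantor correction: expected observed proportion of
    differences for a target per-site distance."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def random_coding_sequence(n_codons: int, rng: np.random.Generator) -> str:
    """Random in-frame coding sequence of sense codons (no stops)."""
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)


def mutate_sequence(
    seq: str,
    frame: int,
    target_dS: float,
    dnds: float,
    rng: np.random.Generator,
) -> str:
    """Mutate a coding sequence toward a target synonymous distance.

    Substitutions are proposed uniformly over in-frame sites at a per-site
    rate equal to the JC-inverted target (so accepted synonymous changes per
    synonymous site land on target_dS in expectation), with the replacement
    base uniform over the three alternatives. Proposals are accepted with
    probability 1 if synonymous and `dnds` if nonsynonymous; proposals that
    would create a stop codon are always rejected.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if any(b not in "ACGT" for b in seq):
        raise ValueError("sequence contains non-ACGT bases")
    if target_dS < 0:
        raise ValueError("target_dS must be >= 0")
    if target_dS == 0:
        return seq

    mu = _p_from_d(target_dS)
    offset = frame % 3
    n_codons = (len(seq) - offset) // 3
    coding_len = n_codons * 3
    if n_codons == 0:
        return seq

    hit = np.flatnonzero(rng.random(coding_len) < mu)
    if hit.size == 0:
        return seq
    alt_choice = rng.integers(0, 3, size=hit.size)
    accept_draw = rng.random(hit.size)

    out = list(seq)
    for k, site in enumerate(hit):
        pos = offset + int(site)
        ci = offset + 3 * ((pos - offset) // 3)
        codon = "".join(out[ci : ci + 3])
        old = out[pos]
        alts = [b for b in BASES if b != old]
        new = alts[alt_choice[k]]
        j = pos - ci
        new_codon = codon[:j] + new + codon[j + 1 :]
        if CODON_TO_AA[new_codon] == "*":
            continue
        synonymous = CODON_TO_AA[new_codon] == CODON_TO_AA[codon]
        if synonymous or accept_draw[k] < dnds:
            out[pos] = new
    return "".join(out)


# ---------------------------------------------------------------------------
# truth construction
# ---------------------------------------------------------------------------

def _diagnostic_sites(truth: SyntheticTruth) -> list:
    """Sites where A2 and D5 differ and every tetraploid homoeolog still
    matches its diploid parent — the genuinely genome-diagnostic sites."""
    snps = []
    a2, d5 = truth.a2, truth.d5
    for i in range(len(a2)):
        a, d = a2[i], d5[i]
        if a == d:
            continue
        if all(truth.a_t[sp][i] == a for sp in truth.a_t) and all(
            truth.d_t[sp][i] == d for sp in truth.d_t
        ):
            snps.append((i, a, d))
    return snps


def build_truth(
    contig_id: str, length: int, config: SimConfig, rng: np.random.Generator
) -> SyntheticTruth:
    """Simulate one contig's lineage sequences (no NRHR, no reads)."""
    n_codons = length // 3
    ancestor = random_coding_sequence(n_codons, rng)
    b = config.branch_dS
    # The A2-vs-D5 target is the total path length: two ancestral half
    # branches plus the two terminal diploid branches.
    half = max(0.0, (config.target_dS_AD - b["A2"] - b["D5"]) / 2.0)
    a_anc = mutate_sequence(ancestor, 0, half, config.target_dnds, rng)
    d_anc = mutate_sequence(ancestor, 0, half, config.target_dnds, rng)
    truth = SyntheticTruth(
        contig_id=contig_id,
        frame=0,
        ancestor=ancestor,
        a2=mutate_sequence(a_anc, 0, b["A2"], config.target_dnds, rng),
        d5=mutate_sequence(d_anc, 0, b["D5"], config.target_dnds, rng),
        a_t={
            sp: mutate_sequence(a_anc, 0, b["AT"], config.target_dnds, rng)
            for sp in TETRAPLOIDS
        },
        d_t={
            sp: mutate_sequence(d_anc, 0, b["DT"], config.target_dnds, rng)
            for sp in TETRAPLOIDS
        },
    )
    truth.true_snps = _diagnostic_sites(truth)
    return truth


def apply_nrhr(
    truth: SyntheticTruth,
    species: str,
    direction: Literal["A->D", "D->A"],
    tract: tuple,
    shared: bool = False,
) -> SyntheticTruth:
    """Overwrite the recipient homoeolog's tract with the donor homoeolog's
    sequence in the named species (both species if `shared`), recording the
    event. Tracts are 0-based half-open; a zero-length tract is a no-op.
    """
    start, end = tract
    if not (0 <= start <= end <= truth.length):
        raise ValueError(f"tract {tract} outside contig bounds [0, {truth.length}]")
    if direction not in ("A->D", "D->A"):
        raise ValueError(f"unknown direction {direction!r}")
    if not shared and species not in TETRAPLOIDS:
        raise ValueError(f"unknown tetraploid species {species!r}")
    if start == end:
        return truth
    targets = list(TETRAPLOIDS) if shared else [species]
    for sp in targets:
        if direction == "A->D":
            donor, rec = truth.a_t[sp], truth.d_t[sp]
            truth.d_t[sp] = rec[:start] + donor[start:end] + rec[end:]
        else:
            donor, rec = truth.d_t[sp], truth.a_t[sp]
            truth.a_t[sp] = rec[:start] + donor[start:end] + rec[end:]
    recipient = "D" if direction == "A->D" else "A"
    truth.true_nrhr.append(
        NRHRTract("shared" if shared else species, recipient, start, end)
    )
    return truth


def plant_nrhr_events(
    truth: SyntheticTruth, config: SimConfig, rng: np.random.Generator
) -> None:
    """Maybe plant one conversion tract on this contig (probability
    nrhr_contig_frac). Tract placement is rejection-sampled so the tract
    covers at least two diagnostic sites and leaves at least one outside,
    the regime in which an event is in principle detectable from reads.
    """
    if rng.random() >= config.nrhr_contig_frac:
        return
    positions = truth.snp_positions()
    if positions.size < 3:
        return
    L = truth.length
    shared = bool(rng.random() < config.nrhr_shared_frac)
    species = TETRAPLOIDS[int(rng.integers(0, len(TETRAPLOIDS)))]
    direction = "A->D" if rng.random() < 0.5 else "D->A"
    for _ in range(50):
        tract_len = min(int(rng.geometric(1.0 / config.nrhr_tract_len_mean)), L - 1)
        if tract_len < 1:
            continue
        start = int(rng.integers(0, L - tract_len + 1))
        end = start + tract_len
        inside = int(np.searchsorted(positions, end) - np.searchsorted(positions, start))
        if inside >= 2 and positions.size - inside >= 1:
            apply_nrhr(truth, species, direction, (start, end), shared=shared)
            return


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def _genome_copies(truth: SyntheticTruth) -> list:
    copies = [(DIPLOID_A, "A", truth.a2), (DIPLOID_D, "D", truth.d5)]
    for sp in TETRAPLOIDS:
        copies.append((sp, "A", truth.a_t[sp]))
        copies.append((sp, "D", truth.d_t[sp]))
    return copies


def _apply_errors(
    bases: np.ndarray, err: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return (bases with substitution errors, phred qualities).

    Bases fall into a high-quality (Q40) and a low-quality (Q12) class whose
    mixture weight reproduces the configured mean error rate; errors are
    drawn per base at the class rate and replace the base uniformly.
    """
    n = bases.size
    if err <= 0:
        return bases, np.full(n, _GOOD_Q, dtype=np.int16)
    w_bad = min(1.0, max(0.0, (err - _GOOD_E) / (_BAD_E - _GOOD_E)))
    bad = rng.random(n) < w_bad
    quals = np.where(bad, _BAD_Q, _GOOD_Q).astype(np.int16)
    e_rate = np.where(bad, _BAD_E, _GOOD_E)
    is_err = rng.random(n) < e_rate
    if is_err.any():
        bases = bases.copy()
        shift = rng.integers(1, 4, size=int(is_err.sum()))
        bases[is_err] = (bases[is_err] + shift) % 4
    return bases, quals


def sample_reads(
    truth: SyntheticTruth,
    platform: Literal["long", "short"],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[AlignedRead]:
    """Shotgun-sample one contig at the configured per-genome-copy coverage.

    Reads carry the species tag, genome of origin (encoded in the read id),
    0-based start offset, and per-base qualities.
    """
    if platform == "long":
        cov, err = config.long_cov, config.long_err
        lo, hi = config.long_read_len
        mean_len = (lo + hi) / 2.0
    elif platform == "short":
        cov, err = config.short_cov, config.short_err
        mean_len = float(config.short_read_len)
    else:
        raise ValueError(f"unknown platform {platform!r}")
    if cov <= 0:
        return []
    L = truth.length
    reads: list[AlignedRead] = []
    for species, origin, seq in _genome_copies(truth):
        enc_seq = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in seq], dtype=np.int8)
        n_reads = max(1, round(L * cov / min(mean_len, L)))
        for i in range(n_reads):
            if platform == "long":
                rlen = min(int(rng.integers(lo, hi + 1)), L)
            else:
                rlen = min(config.short_read_len, L)
            start = int(rng.integers(0, L - rlen + 1))
            bases, quals = _apply_errors(enc_seq[start : start + rlen], err, rng)
            reads.append(
                AlignedRead(
                    read_id=f"{species}|{truth.contig_id}|{origin}|{platform[0]}{i}",
                    species=species,
                    platform=platform,
                    start=start,
                    bases="".join("ACGT"[b] for b in bases),
                    quals=quals,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# dataset assembly and I/O
# ---------------------------------------------------------------------------

def simulate_truths(config: SimConfig, rng: np.random.Generator) -> dict:
    """Simulate lineage sequences (with NRHR) for every contig; no reads."""
    truths = {}
    width = len(str(max(config.n_contigs, 1)))
    for i in range(config.n_contigs):
        length = int(rng.normal(config.contig_len_mean, config.contig_len_sd))
        length = max(config.min_contig_len, length)
        length -= length % 3
        cid = f"contig{str(i).zfill(width)}"
        truth = build_truth(cid, length, config, rng)
        plant_nrhr_events(truth, config, rng)
        truths[cid] = truth
    return truths


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Full dataset: truths plus per-contig alignments for both platforms."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths = simulate_truths(config, rng)
    alignments = {}
    for cid, truth in truths.items():
        aln = ContigAlignment(cid, truth.length)
        for platform in ("long", "short"):
            for read in sample_reads(truth, platform, config, rng):
                aln.add_read(read)
        alignments[cid] = aln
    return SimulatedDataset(config=config, truths=truths, alignments=alignments)


def _write_fasta(records: Iterable[tuple], path: Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def _read_fasta(path: Path) -> dict:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Emit the dataset as plain-text files: reference and truth FASTA,
    per-platform FASTQ, placement TSV, truth tables and the YAML config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths = dataset.truths

    _write_fasta(
        ((cid, truths[cid].ancestor) for cid in sorted(truths)), out / "refs.fasta"
    )
    seq_records = []
    for cid in sorted(truths):
        t = truths[cid]
        seq_records.append((f"{cid}|A2", t.a2))
        seq_records.append((f"{cid}|D5", t.d5))
        for sp in TETRAPLOIDS:
            seq_records.append((f"{cid}|{sp}|A", t.a_t[sp]))
            seq_records.append((f"{cid}|{sp}|D", t.d_t[sp]))
    _write_fasta(seq_records, out / "truth_seqs.fasta")

    for platform in ("long", "short"):
        with open(out / f"reads_{platform}.fastq", "w") as fh:
            for cid in sorted(dataset.alignments):
                for r in dataset.alignments[cid].reads:
                    if r.platform != platform:
                        continue
                    q = "".join(chr(int(v) + 33) for v in r.quals) if r.quals is not None else "I" * len(r.bases)
                    fh.write(f"@{r.read_id}\n{r.bases}\n+\n{q}\n")

    write_placement_tsv(dataset.alignments, out / "placement.tsv")

    with open(out / "truth_snps.tsv", "w") as fh:
        fh.write("contig\tpos\ta_allele\td_allele\n")
        for cid in sorted(truths):
            for pos, a, d in truths[cid].true_snps:
                fh.write(f"{cid}\t{pos}\t{a}\t{d}\n")
    with open(out / "truth_nrhr.tsv", "w") as fh:
        fh.write("contig\tscope\trecipient\tstart\tend\n")
        for cid in sorted(truths):
            for ev in truths[cid].true_nrhr:
                fh.write(f"{cid}\t{ev.scope}\t{ev.recipient}\t{ev.start}\t{ev.end}\n")
    with open(out / "frames.tsv", "w") as fh:
        fh.write("contig\tframe\n")
        for cid in sorted(truths):
            fh.write(f"{cid}\t{truths[cid].frame}\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(dataset.config), fh, sort_keys=True)


def load_dataset(out_dir: str | Path) -> SimulatedDataset:
    """Reload a dataset written by :func:`write_dataset` without loss."""
    out = Path(out_dir)
    with open(out / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["long_read_len"] = tuple(raw["long_read_len"])
    config = SimConfig(**raw)

    refs = _read_fasta(out / "refs.fasta")
    seqs = _read_fasta(out / "truth_seqs.fasta")
    truths = {}
    for cid, anc in refs.items():
        truths[cid] = SyntheticTruth(
            contig_id=cid,
            frame=0,
            ancestor=anc,
            a2=seqs[f"{cid}|A2"],
            d5=seqs[f"{cid}|D5"],
            a_t={sp: seqs[f"{cid}|{sp}|A"] for sp in TETRAPLOIDS},
            d_t={sp: seqs[f"{cid}|{sp}|D"] for sp in TETRAPLOIDS},
        )
    with open(out / "frames.tsv") as fh:
        next(fh)
        for line in fh:
            cid, frame = line.split()
            truths[cid].frame = int(frame)
    with open(out / "truth_snps.tsv") as fh:
        next(fh)
        for line in fh:
            cid, pos, a, d = line.split()
            truths[cid].true_snps.append((int(pos), a, d))
    with open(out / "truth_nrhr.tsv") as fh:
        next(fh)
        for line in fh:
            cid, scope, recipient, start, end = line.split()
            truths[cid].true_nrhr.append(
                NRHRTract(scope, recipient, int(start), int(end))
            )

    lengths = {cid: len(seq) for cid, seq in refs.items()}
    alignments = load_alignment(out / "placement.tsv", lengths=lengths)
    return SimulatedDataset(config=config, truths=truths, alignments=alignments)
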