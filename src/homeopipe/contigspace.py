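"""Per-contig multi-species read alignments and column-wise base counting.

The data model is deliberately simple: an EST contig is a coordinate frame,
and every read is stored reference-oriented as a gapless base string placed at
a 0-based offset (the assemblies modelled here are substitution-only; indel
columns are out of scope and reads with indels in their CIGAR are masked out
of the columns they cannot represent). Two on-disk representations are
supported: plain SAM (mandatory fields; read groups or ``species|``-prefixed
read names resolve provenance) and a flat placement TSV, which is the native
format of the simulator.

Coordinates are 0-based half-open everywhere in memory; only exported
VCF-style tables are 1-based.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pysam

from ._codon import BASES, BASE_INDEX

#: default species labels: two diploids and two allotetraploids
DEFAULT_SPECIES = ("A2", "D5", "AD1", "AD2")
DIPLOID_A = "A2"
DIPLOID_D = "D5"
TETRAPLOIDS = ("AD1", "AD2")

PLACEMENT_COLUMNS = ("read_id", "contig", "species", "platform", "start", "bases", "quals")


class SpeciesResolutionError(ValueError):
    """A read could not be assigned to a species label."""

    def __init__(self, read_ids: Sequence[str]):
        self.read_ids = list(read_ids)
        preview = ", ".join(self.read_ids[:5])
        super().__init__(
            f"{len(self.read_ids)} read(s) could not be resolved to a species "
            f"(e.g. {preview}); provide a species_map or species-prefixed names"
        )


@dataclass
class AlignedRead:
    """One read placed on a contig, reference-oriented and gapless."""

    read_id: str
    species: str
    platform: str  # "long" | "short"
    start: int
    bases: str
    quals: np.ndarray | None = None  # phred values, same length as bases

    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"read {self.read_id}: negative start {self.start}")
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ValueError(f"read {self.read_id}: quals/bases length mismatch")

    @property
    def end(self) -> int:
        return self.start + len(self.bases)

    def encoded(self) -> np.ndarray:
        """Bases as int codes (A,C,G,T -> 0..3; anything else -> -1)."""
        if self._encoded is None:
            codes = np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)
            enc = np.full(codes.shape, -1, dtype=np.int8)
            for b, i in BASE_INDEX.items():
                enc[codes == ord(b)] = i
            self._encoded = enc
        return self._encoded

    def base_at(self, pos: int) -> str | None:
        """Base at contig position `pos`, or None if not covered / non-ACGT."""
        if not (self.start <= pos < self.end):
            return None
        b = self.bases[pos - self.start]
        return b if b in BASE_INDEX else None

    def qual_at(self, pos: int) -> float | None:
        if self.quals is None or not (self.start <= pos < self.end):
            return None
        return float(self.quals[pos - self.start])


class ContigAlignment:
    """A stack of reads over one contig reference.

    Column counting is the workhorse for consensus building: counts are per
    (species subset, platform subset) and cached as an (L, 4) matrix.
    """

    def __init__(self, contig_id: str, length: int, reads: Iterable[AlignedRead] = ()):
        if length <= 0:
            raise ValueError(f"contig {contig_id}: non-positive length {length}")
        self.contig_id = contig_id
        self.length = length
        self.reads: list[AlignedRead] = []
        self._matrices: dict[tuple, np.ndarray] = {}
        for r in reads:
            self.add_read(r)

    def add_read(self, read: AlignedRead) -> None:
        if read.end > self.length:
            raise ValueError(
                f"read {read.read_id} extends past contig {self.contig_id} "
                f"({read.end} > {self.length})"
            )
        self.reads.append(read)
        self._matrices.clear()

    def __len__(self) -> int:
        return len(self.reads)

    def iter_reads(
        self, species: str | Sequence[str] | None = None, platform: str | None = None
    ) -> Iterator[AlignedRead]:
        wanted = None if species is None else (
            {species} if isinstance(species, str) else set(species)
        )
        for r in self.reads:
            if wanted is not None and r.species not in wanted:
                continue
            if platform is not None and r.platform != platform:
                continue
            yield r

    def count_matrix(
        self, species: str | Sequence[str] | None = None, platform: str | None = None
    ) -> np.ndarray:
        """(length, 4) matrix of ACGT counts for the selected read group."""
        key_sp = species if isinstance(species, (str, type(None))) else tuple(sorted(species))
        key = (key_sp, platform)
        mat = self._matrices.get(key)
        if mat is None:
            mat = np.zeros((self.length, 4), dtype=np.int32)
            for r in self.iter_reads(species, platform):
                enc = r.encoded()
                valid = enc >= 0
                pos = np.arange(r.start, r.end)[valid]
                np.add.at(mat, (pos, enc[valid].astype(np.intp)), 1)
            self._matrices[key] = mat
        return mat

    def column_counts(
        self,
        pos: int,
        species: str | Sequence[str] | None = None,
        platform: str | None = None,
    ) -> dict[str, int]:
        """Base -> count map at one column, restricted to a read group.

        Only reads covering `pos` with an unambiguous base contribute.
        """
        if not (0 <= pos < self.length):
            raise IndexError(f"position {pos} outside contig {self.contig_id} [0, {self.length})")
        row = self.count_matrix(species, platform)[pos]
        return {BASES[i]: int(c) for i, c in enumerate(row) if c > 0}


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _quals_to_str(quals: np.ndarray | None) -> str:
    if quals is None:
        return "."
    return "".join(chr(int(q) + 33) for q in quals)


def _quals_from_str(s: str) -> np.ndarray | None:
    if s == "." or s == "":
        return None
    return np.array([ord(c) - 33 for c in s], dtype=np.int16)


def write_placement_tsv(
    alignments: Mapping[str, "ContigAlignment"], path: str | Path
) -> None:
    """Write the flat placement table (native TSV dialect, 0-based starts)."""
    with open(path, "w") as fh:
        fh.write("\t".join(PLACEMENT_COLUMNS) + "\n")
        for contig_id in sorted(alignments):
            aln = alignments[contig_id]
            for r in aln.reads:
                fh.write(
                    f"{r.read_id}\t{contig_id}\t{r.species}\t{r.platform}\t"
                    f"{r.start}\t{r.bases}\t{_quals_to_str(r.quals)}\n"
                )


def _load_placement_tsv(
    path: str | Path, lengths: Mapping[str, int]
) -> dict[str, ContigAlignment]:
    alignments = {
        cid: ContigAlignment(cid, length) for cid, length in lengths.items()
    }
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != PLACEMENT_COLUMNS:
            raise ValueError(f"unrecognized placement TSV header in {path}")
        for line in fh:
            read_id, contig, species, platform, start, bases, quals = (
                line.rstrip("\n").split("\t")
            )
            if contig not in alignments:
                raise ValueError(f"placement references unknown contig {contig}")
            alignments[contig].add_read(
                AlignedRead(
                    read_id=read_id,
                    species=species,
                    platform=platform,
                    start=int(start),
                    bases=bases,
                    quals=_quals_from_str(quals),
                )
            )
    return alignments


def _resolve_species(
    rec: pysam.AlignedSegment,
    rg_species: Mapping[str, str],
    species_map: Mapping[str, str] | None,
    known: Sequence[str],
) -> str | None:
    if rec.has_tag("RG"):
        rg = rec.get_tag("RG")
        if rg in rg_species:
            return rg_species[rg]
        if species_map and rg in species_map:
            return species_map[rg]
    name = rec.query_name or ""
    prefix = name.split("|", 1)[0]
    if species_map and prefix in species_map:
        return species_map[prefix]
    if prefix in known:
        return prefix
    return None


def _load_sam(
    path: str | Path,
    species_map: Mapping[str, str] | None,
    known_species: Sequence[str],
    default_platform: str,
) -> dict[str, ContigAlignment]:
    alignments: dict[str, ContigAlignment] = {}
    unresolved: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for name, length in zip(sam.references, sam.lengths):
            alignments[name] = ContigAlignment(name, length)
        rg_species = {
            rg.get("ID"): rg["SM"]
            for rg in sam.header.to_dict().get("RG", [])
            if "SM" in rg
        }
        for rec in sam:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            species = _resolve_species(rec, rg_species, species_map, known_species)
            if species is None:
                unresolved.append(rec.query_name or "<unnamed>")
                continue
            # Reference-oriented gapless projection: walk aligned pairs and
            # keep match columns only (soft-clips never appear; read bases at
            # insertions are dropped; deleted reference columns are not
            # representable in a gapless read, so reads with deletions are
            # split at the first deletion and the 5' block kept).
            seq = rec.query_sequence
            quals = rec.query_qualities
            bases: list[str] = []
            qvals: list[int] = []
            start = rec.reference_start
            expect = start
            for qpos, rpos in rec.get_aligned_pairs():
                if qpos is None or rpos is None:
                    if rpos is not None and rpos >= expect and bases:
                        break  # deletion: keep the leading block
                    continue
                if rpos != expect and bases:
                    break
                if not bases:
                    start = rpos
                    expect = rpos
                bases.append(seq[qpos])
                qvals.append(quals[qpos] if quals is not None else -1)
                expect = rpos + 1
            if not bases:
                continue
            qarr = (
                np.array(qvals, dtype=np.int16)
                if quals is not None
                else None
            )
            platform = default_platform
            if rec.has_tag("XP"):
                platform = str(rec.get_tag("XP"))
            alignments[rec.reference_name].add_read(
                AlignedRead(
                    read_id=rec.query_name or "<unnamed>",
                    species=species,
                    platform=platform,
                    start=start,
                    bases="".join(bases),
                    quals=qarr,
                )
            )
    if unresolved:
        raise SpeciesResolutionError(unresolved)
    return alignments


def load_alignment(
    path: str | Path,
    species_map: Mapping[str, str] | None = None,
    lengths: Mapping[str, int] | None = None,
    known_species: Sequence[str] = DEFAULT_SPECIES,
    default_platform: str = "long",
) -> dict[str, ContigAlignment]:
    """Load per-contig alignments from SAM or a placement TSV.

    SAM input takes contig lengths from @SQ lines and resolves species from
    read groups (SM field), a ``species_map`` keyed by read-group ID or read
    name prefix, or a ``species|…`` read-name prefix. TSV input (the
    simulator's native dialect) requires `lengths`.
    """
    path = Path(path)
    if path.suffix.lower() == ".sam":
        return _load_sam(path, species_map, known_species, default_platform)
    if lengths is None:
        raise ValueError("placement TSV input requires contig lengths")
    return _load_placement_tsv(path, lengths)


def write_pileup_tsv(aln: ContigAlignment, path: str | Path) -> None:
    """Debug dump: per-column per-species base counts (1-based positions)."""
    species = sorted({r.species for r in aln.reads})
    with open(path, "w") as fh:
        fh.write("contig\tpos\t" + "\t".join(species) + "\n")
        mats = {sp: aln.count_matrix(sp) for sp in species}
        for pos in range(aln.length):
            cells = []
            for sp in species:
                row = mats[sp][pos]
                cells.append(
                    ",".join(f"{BASES[i]}:{row[i]}" for i in range(4) if row[i])
                    or "."
                )
            fh.write(f"{aln.contig_id}\t{pos + 1}\t" + "\t".join(cells) + "\n")
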