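"""Genomic containers and I/O for stranded 5'-end count tracks.

HydEn-seq maps 5' DNA ends created by alkaline hydrolysis at embedded
ribonucleotides.  The pipeline works on dense per-nucleotide count arrays,
one per strand per chromosome, read from and written to per-strand bedGraph
files.  Because a hydrolytic 5' end sits one nucleotide 3' of the
ribonucleotide that caused it, raw end tracks are converted to implied
ribonucleotide tracks by shifting every count one nucleotide upstream
(relative to the strand the fragment maps to).

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

Semantics = Literal["raw-5p-ends", "implied-rnmp", "normalized"]

VARIANT_POLYMERASES = ("none", "pol1-L868M", "pol2-M644G", "pol3-L612M")
POL2_ALLELES = ("POL2", "pol2-4", "pol2-16")
RER_STATES = ("RER+", "RER-")

#: variant allele -> replicase it makes ribonucleotide-promiscuous
VARIANT_TO_POL = {
    "pol1-L868M": "alpha",
    "pol3-L612M": "delta",
    "pol2-M644G": "epsilon",
}


@dataclass
class Genome:
    """Reference genome: ordered chromosome lengths plus optional sequence."""

    lengths: dict[str, int]
    sequence: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome has no chromosomes")
        for name, n in self.lengths.items():
            if n <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {n}")
        if self.sequence is not None:
            if set(self.sequence) != set(self.lengths):
                raise ValueError("sequence chromosomes do not match declared lengths")
            for name, seq in self.sequence.items():
                if len(seq) != self.lengths[name]:
                    raise ValueError(
                        f"sequence length {len(seq)} != declared {self.lengths[name]} "
                        f"for chromosome {name!r}"
                    )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


@dataclass
class StrandedEndTrack:
    """Dense per-strand 5'-end counts over a genome.

    ``counts[chrom]`` is a pair ``(forward, reverse)`` of float arrays of
    chromosome length.  Counts are stored as reals so normalized tracks share
    the type; ``semantics`` guards against double-shifting/normalizing.
    """

    genome: Genome
    counts: dict[str, tuple[np.ndarray, np.ndarray]]
    semantics: Semantics = "raw-5p-ends"
    size_factor: float | None = None

    def __post_init__(self) -> None:
        if set(self.counts) != set(self.genome.lengths):
            raise ValueError("track chromosomes do not match genome")
        for chrom, (fwd, rev) in self.counts.items():
            n = self.genome.lengths[chrom]
            if len(fwd) != n or len(rev) != n:
                raise ValueError(f"count array length mismatch on {chrom!r}")
            if np.any(fwd < 0) or np.any(rev < 0):
                raise ValueError(f"negative counts on {chrom!r}")

    @classmethod
    def zeros(cls, genome: Genome, semantics: Semantics = "raw-5p-ends") -> "StrandedEndTrack":
        counts = {
            c: (np.zeros(n, dtype=float), np.zeros(n, dtype=float))
            for c, n in genome.lengths.items()
        }
        return cls(genome=genome, counts=counts, semantics=semantics)

    def total(self) -> float:
        return float(sum(fwd.sum() + rev.sum() for fwd, rev in self.counts.values()))

    def copy(self) -> "StrandedEndTrack":
        return StrandedEndTrack(
            genome=self.genome,
            counts={c: (f.copy(), r.copy()) for c, (f, r) in self.counts.items()},
            semantics=self.semantics,
            size_factor=self.size_factor,
        )


@dataclass(frozen=True)
class SampleSpec:
    """One HydEn-seq library: genotype and replicate identity."""

    sample_id: str
    variant_polymerase: str = "none"
    pol2_allele: str = "POL2"
    rer: str = "RER-"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.variant_polymerase not in VARIANT_POLYMERASES:
            raise ValueError(f"unknown variant polymerase {self.variant_polymerase!r}")
        if self.pol2_allele not in POL2_ALLELES:
            raise ValueError(f"unknown POL2 allele {self.pol2_allele!r}")
        if self.rer not in RER_STATES:
            raise ValueError(f"unknown RER status {self.rer!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def genotype(self) -> tuple[str, str, str]:
        return (self.variant_polymerase, self.pol2_allele, self.rer)


@dataclass(frozen=True)
class Origin:
    """One oriented replication origin anchored at the 5' end of its ACS."""

    chrom: str
    anchor: int
    strand: str
    name: str


@dataclass
class OriginSet:
    """Oriented ACS anchors; position 0 is the 5' end of the ACS on its strand."""

    entries: list[Origin] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [o.name for o in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("origin names are not unique")
        for o in self.entries:
            if o.strand not in "+-":
                raise ValueError(f"origin {o.name!r} has invalid strand {o.strand!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Origin]:
        return iter(self.entries)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_genome(fasta_path: str | Path) -> Genome:
    """Read a FASTA reference; sequences upper-cased, non-ACGT mapped to N."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {fasta_path}")
    lengths: dict[str, int] = {}
    sequence: dict[str, str] = {}
    table = str.maketrans(
        {c: "N" for c in set(map(chr, range(65, 91))) - set("ACGTN")}
    )
    for rec in records:
        if rec.id in lengths:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {fasta_path}")
        seq = str(rec.seq).upper().translate(table)
        lengths[rec.id] = len(seq)
        sequence[rec.id] = seq
    return Genome(lengths=lengths, sequence=sequence)


def write_genome(genome: Genome, fasta_path: str | Path) -> None:
    if genome.sequence is None:
        raise ValueError("genome has no sequence to write")
    records = [
        SeqRecord(Seq(genome.sequence[c]), id=c, description="")
        for c in genome.chromosomes
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def _read_bedgraph_into(array_by_chrom: Mapping[str, np.ndarray], path: str | Path) -> None:
    df = pd.read_csv(
        str(path),
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    if df.empty:
        return
    if (df["value"] < 0).any():
        raise ValueError(f"negative value in bedGraph {path}")
    for chrom, sub in df.groupby("chrom", sort=False):
        if chrom not in array_by_chrom:
            raise ValueError(f"bedGraph {path} references unknown chromosome {chrom!r}")
        arr = array_by_chrom[chrom]
        starts = sub["start"].to_numpy(dtype=np.int64)
        ends = sub["end"].to_numpy(dtype=np.int64)
        vals = sub["value"].to_numpy(dtype=float)
        if (starts < 0).any() or (ends > len(arr)).any() or (starts >= ends).any():
            raise ValueError(f"out-of-bounds or empty interval in bedGraph {path}")
        # overlapping intervals sum; difference-array trick keeps this O(n)
        diff = np.zeros(len(arr) + 1)
        np.add.at(diff, starts, vals)
        np.add.at(diff, ends, -vals)
        arr += np.cumsum(diff[:-1])


def read_end_track(
    fwd_bedgraph: str | Path,
    rev_bedgraph: str | Path,
    genome: Genome,
    semantics: Semantics = "raw-5p-ends",
) -> StrandedEndTrack:
    """Read one sample's per-strand bedGraph pair into dense arrays."""
    track = StrandedEndTrack.zeros(genome, semantics=semantics)
    _read_bedgraph_into({c: fr[0] for c, fr in track.counts.items()}, fwd_bedgraph)
    _read_bedgraph_into({c: fr[1] for c, fr in track.counts.items()}, rev_bedgraph)
    return track


def _write_bedgraph(array_by_chrom: Mapping[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, arr in array_by_chrom.items():
            nz = np.flatnonzero(arr)
            if nz.size == 0:
                continue
            # merge runs of equal adjacent values into intervals
            breaks = np.flatnonzero(np.diff(nz) != 1)
            run_starts = np.concatenate(([0], breaks + 1))
            run_ends = np.concatenate((breaks, [nz.size - 1]))
            for rs, re_ in zip(run_starts, run_ends):
                pos = nz[rs : re_ + 1]
                vals = arr[pos]
                change = np.flatnonzero(np.diff(vals) != 0)
                seg_starts = np.concatenate(([0], change + 1))
                seg_ends = np.concatenate((change, [vals.size - 1]))
                for ss, se in zip(seg_starts, seg_ends):
                    v = vals[ss]
                    v_repr = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{pos[ss]}\t{pos[se] + 1}\t{v_repr}\n")


def write_end_track(track: StrandedEndTrack, fwd_path: str | Path, rev_path: str | Path) -> None:
    """Write a track as a per-strand bedGraph pair (0-based half-open)."""
    _write_bedgraph({c: fr[0] for c, fr in track.counts.items()}, fwd_path)
    _write_bedgraph({c: fr[1] for c, fr in track.counts.items()}, rev_path)


def read_origins(bed_path: str | Path, genome: Genome) -> OriginSet:
    """Read oriented origins from BED6.

    The anchor is the 5' end of the ACS on its annotated strand: BED start
    for '+' entries, BED end − 1 for '−' entries.
    """
    df = pd.read_csv(
        str(bed_path),
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if df["strand"].isna().any() or not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"BED6 origin file {bed_path} has missing/invalid strand")
    entries = []
    for row in df.itertuples(index=False):
        anchor = int(row.start) if row.strand == "+" else int(row.end) - 1
        if row.chrom not in genome:
            raise ValueError(f"origin {row.name!r} on unknown chromosome {row.chrom!r}")
        if not (0 <= anchor < genome.lengths[row.chrom]):
            raise ValueError(f"origin {row.name!r} anchor {anchor} outside genome")
        entries.append(Origin(chrom=row.chrom, anchor=anchor, strand=row.strand, name=str(row.name)))
    return OriginSet(entries=entries)


def write_origins(origins: OriginSet, bed_path: str | Path, acs_length: int = 33) -> None:
    """Write origins as BED6 with an interval of ``acs_length`` from the anchor."""
    with open(bed_path, "w") as fh:
        for o in origins:
            if o.strand == "+":
                start, end = o.anchor, o.anchor + acs_length
            else:
                start, end = o.anchor - acs_length + 1, o.anchor + 1
            fh.write(f"{o.chrom}\t{start}\t{end}\t{o.name}\t0\t{o.strand}\n")


SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "variant_polymerase",
    "pol2_allele",
    "rer",
    "replicate",
    "fwd_path",
    "rev_path",
]


def read_sample_sheet(tsv_path: str | Path) -> pd.DataFrame:
    """Read the TSV sample sheet; validates genotype columns and uniqueness."""
    df = pd.read_csv(str(tsv_path), sep="\t", dtype=str)
    missing = set(SAMPLE_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    df["replicate"] = df["replicate"].astype(int)
    for row in df.itertuples(index=False):
        SampleSpec(
            sample_id=row.sample_id,
            variant_polymerase=row.variant_polymerase,
            pol2_allele=row.pol2_allele,
            rer=row.rer,
            replicate=row.replicate,
        )
    keys = df[["variant_polymerase", "pol2_allele", "rer", "replicate"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (genotype, replicate) entries in sample sheet")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    return df


# ---------------------------------------------------------------------------
# raw 5' ends -> implied ribonucleotide positions
# ---------------------------------------------------------------------------

def implied_rnmp_positions(track: StrandedEndTrack) -> StrandedEndTrack:
    """Shift 5'-end counts one nucleotide upstream to the implied ribonucleotide.

    Forward-strand counts at p move to p−1, reverse-strand counts at p move to
    p+1 (upstream is strand-relative).  Counts shifted off a chromosome end are
    dropped and logged.  Input must carry raw 5'-end semantics.
    """
    if track.semantics != "raw-5p-ends":
        raise ValueError(f"expected raw 5'-end track, got semantics={track.semantics!r}")
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    dropped = 0.0
    for chrom, (fwd, rev) in track.counts.items():
        new_fwd = np.zeros_like(fwd)
        new_rev = np.zeros_like(rev)
        new_fwd[:-1] = fwd[1:]
        dropped += float(fwd[0])
        new_rev[1:] = rev[:-1]
        dropped += float(rev[-1])
        out[chrom] = (new_fwd, new_rev)
    if dropped:
        logger.info("implied_rnmp_positions: dropped %.0f counts at chromosome ends", dropped)
    return StrandedEndTrack(
        genome=track.genome, counts=out, semantics="implied-rnmp", size_factor=track.size_factor
    )
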