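"""Library-size normalization on restriction-site 5'-end counts.

SbfI digestion of genomic DNA before library preparation plants 5' ends at
every recognition site, at sequence-determined positions, in every sample.
Counts at those predicted end positions behave like a panel of internal
standards, so per-sample size factors are computed from them with the
median-of-ratios estimator (as in DESeq): per site-strand entry, the ratio of
each sample's count to the across-sample geometric mean; entries with a zero
in any sample are excluded; the factor is the median retained ratio.
Normalized tracks are the raw counts divided by the factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracks import Genome, StrandedEndTrack

#: SbfI recognition sequence (palindromic) and cut geometry CCTGCA^GG:
#: cleavage leaves a forward-strand 5' end 6 nt into the site and a
#: reverse-strand 5' end 2 nt into the site (4-nt 3' overhang).
RECOGNITION_SEQUENCE = "CCTGCAGG"
CUT_OFFSET_FWD = 6
CUT_OFFSET_REV = 2


@dataclass
class RestrictionSiteSet:
    """Occurrences of a recognition sequence with predicted cleavage 5' ends."""

    recognition_sequence: str
    sites: list[tuple[str, int]] = field(default_factory=list)
    fwd_end_offset: int = CUT_OFFSET_FWD
    rev_end_offset: int = CUT_OFFSET_REV

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def predicted_end_positions(self) -> list[tuple[str, int, int]]:
        """Per site: (chrom, forward-strand end coord, reverse-strand end coord)."""
        return [
            (chrom, s + self.fwd_end_offset, s + self.rev_end_offset)
            for chrom, s in self.sites
        ]


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios factors and the entry count used."""

    factors: dict[str, float]
    n_sites_used: int

    def __getitem__(self, sample_id: str) -> float:
        return self.factors[sample_id]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": list(self.factors),
                "size_factor": list(self.factors.values()),
                "n_sites_used": self.n_sites_used,
            }
        )


def find_sbfi_sites(
    genome: Genome,
    recognition_sequence: str = RECOGNITION_SEQUENCE,
    fwd_end_offset: int = CUT_OFFSET_FWD,
    rev_end_offset: int = CUT_OFFSET_REV,
) -> RestrictionSiteSet:
    """Scan the genome for recognition-site occurrences (forward strand only;
    the default SbfI motif is palindromic so one scan covers both strands)."""
    if genome.sequence is None:
        raise ValueError("genome has no sequence; cannot locate restriction sites")
    sites: list[tuple[str, int]] = []
    for chrom in genome.chromosomes:
        seq = genome.sequence[chrom]
        start = seq.find(recognition_sequence)
        while start != -1:
            sites.append((chrom, start))
            start = seq.find(recognition_sequence, start + 1)
    return RestrictionSiteSet(
        recognition_sequence=recognition_sequence,
        sites=sites,
        fwd_end_offset=fwd_end_offset,
        rev_end_offset=rev_end_offset,
    )


def site_end_counts(
    track: StrandedEndTrack, sites: RestrictionSiteSet, window_bp: int = 0
) -> np.ndarray:
    """Per-site, per-strand 5'-end counts at predicted cleavage positions.

    Returns a vector ordered by (chromosome order, site coordinate, then
    forward before reverse strand).  ``window_bp`` widens each predicted end
    to a ±window sum, which absorbs end-repair slop in real libraries.
    Counts are taken from the supplied (raw, unshifted) track: restriction
    ends are not ribonucleotide-derived, so the implied-ribonucleotide shift
    must not be applied first.
    """
    if track.semantics != "raw-5p-ends":
        raise ValueError("site_end_counts expects a raw 5'-end track")
    chrom_order = {c: i for i, c in enumerate(track.genome.chromosomes)}
    ordered = sorted(sites.predicted_end_positions, key=lambda t: (chrom_order[t[0]], t[1]))
    out = np.empty(2 * len(ordered))
    for i, (chrom, fwd_pos, rev_pos) in enumerate(ordered):
        fwd, rev = track.counts[chrom]
        n = len(fwd)
        lo, hi = max(0, fwd_pos - window_bp), min(n, fwd_pos + window_bp + 1)
        out[2 * i] = fwd[lo:hi].sum()
        lo, hi = max(0, rev_pos - window_bp), min(n, rev_pos + window_bp + 1)
        out[2 * i + 1] = rev[lo:hi].sum()
    return out


def median_of_ratios(count_matrix: pd.DataFrame | np.ndarray, sample_ids: list[str] | None = None) -> SizeFactors:
    """Median-of-ratios size factors from a samples × entries count matrix.

    Per entry, the geometric mean across samples is the reference; entries
    with a zero count in any sample are excluded; each sample's factor is the
    median of its count/reference ratios over retained entries (mean of the
    two central values for an even count).
    """
    if isinstance(count_matrix, pd.DataFrame):
        sample_ids = list(count_matrix.index)
        mat = count_matrix.to_numpy(dtype=float)
    else:
        mat = np.asarray(count_matrix, dtype=float)
        if sample_ids is None:
            sample_ids = [f"sample{i}" for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two samples")
    keep = np.all(mat > 0, axis=0)
    n_used = int(keep.sum())
    if n_used == 0:
        raise ValueError(
            "no restriction-site entry has nonzero counts in every sample; "
            "size factors are undefined (check library depth or widen window_bp)"
        )
    sub = mat[:, keep]
    geomean = np.exp(np.mean(np.log(sub), axis=0))
    ratios = sub / geomean
    factors = np.median(ratios, axis=1)
    return SizeFactors(
        factors={sid: float(f) for sid, f in zip(sample_ids, factors)},
        n_sites_used=n_used,
    )


def apply_size_factor(track: StrandedEndTrack, factor: float) -> StrandedEndTrack:
    """Divide every count by the sample's size factor; marks the track normalized."""
    if factor <= 0:
        raise ValueError("size factor must be positive")
    counts = {c: (f / factor, r / factor) for c, (f, r) in track.counts.items()}
    return StrandedEndTrack(
        genome=track.genome,
        counts=counts,
        semantics="normalized",
        size_factor=factor,
    )
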