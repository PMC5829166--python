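"""Forward simulation of the HydEn-seq replication-enzymology experiment.

The simulator builds a random genome with planted SbfI sites and evenly
spaced oriented origins, replicates it in many genome copies under one of
two origin-initiation models, embeds ribonucleotides with genotype-dependent
propensities, applies ribonucleotide excision repair, and samples sequenced
5' ends — emitting both standard-format pipeline inputs (FASTA, BED6,
per-strand bedGraph, TSV sample sheet) and exact truth labels for every
sampled end, so every analysis stage can be verified against planted ground
truth.

Replication geometry (per genome copy, per fired origin, oriented so the
ACS reads 5'->3' from offset 0):

* Each origin fires with ``origin_efficiency``; replicon boundaries lie at
  midpoints between adjacent fired origins (chromosome ends terminate).
* The oriented-downstream fork's leading strand starts at offset
  X ~ Normal(alpha_start_mean, alpha_start_sd) (or geometrically, with
  per-bp priming probability ``p_prime`` while ssDNA is exposed); the
  oriented-upstream fork mirrors an independent draw around the axis of
  strand symmetry.
* Model 1: the leading strand is [Pol alpha primer][Pol delta tract
  L ~ Normal(delta_tract_mean, delta_tract_sd)][Pol epsilon to the
  boundary] — Pol delta initiates leading-strand synthesis and hands off
  to Pol epsilon on collision with the opposing replisome.
* Model 2: the leading strand is [Pol alpha primer][Pol epsilon ...], and
  the first Okazaki fragment of the converging fork nick-translates a
  Pol delta tract of length E over the leading 5' terminus, displacing the
  primer.  Both models plant origin-proximal Pol delta synthesis.
* Lagging strands are tiled by Okazaki fragments
  (length ~ Normal(okazaki_mean, okazaki_sd), truncated), each a Pol alpha
  primer plus Pol delta body.

End formation: each nascent nucleotide synthesized by polymerase p carries a
ribonucleotide with probability rho[p, allele] * rate_scale; a ribonucleotide
survives RER with probability ``rer_retention_minus``/``..._plus``; alkaline
hydrolysis of a surviving ribonucleotide at position q yields a 5' end at
q+1 (forward strand) or q-1 (reverse strand), the exact inverse of the
pipeline's implied-ribonucleotide shift; chromosome-terminal ribonucleotides
yield no end.  Uniform background ends (free ends from nicks and shear) and
SbfI cleavage ends complete the library, and ``depth`` ends are drawn
multinomially.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .fractions import PolymeraseRates
from .normalization import RECOGNITION_SEQUENCE, find_sbfi_sites
from .tracks import (
    Genome,
    Origin,
    OriginSet,
    SampleSpec,
    StrandedEndTrack,
    VARIANT_TO_POL,
    write_end_track,
    write_genome,
    write_origins,
)

POL_NAMES = ("alpha", "delta", "epsilon")
CLASS_NAMES = ("leading", "lagging-primer", "lagging-body", "origin-delta-tract")
#: (polymerase, tract class) combinations that occur in simulated molecules
LABELS = (
    ("alpha", "leading"),
    ("epsilon", "leading"),
    ("alpha", "lagging-primer"),
    ("delta", "lagging-body"),
    ("delta", "origin-delta-tract"),
)


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment."""

    seed: int
    n_chromosomes: int = 1
    chromosome_length: int = 200_000
    n_origins_per_chromosome: int = 4
    origin_efficiency: float = 1.0
    model: str = "model1"  # "model1" | "model2"
    okazaki_mean: float = 165.0
    okazaki_sd: float = 30.0
    alpha_primer_length: int = 15
    delta_tract_mean: float = 160.0
    delta_tract_sd: float = 8.0
    priming_mode: str = "gaussian_start"  # "gaussian_start" | "geometric"
    alpha_start_mean: float = -60.0
    alpha_start_sd: float = 10.0
    p_prime: float = 0.001
    symmetry_axis: float = 45.0
    rates: PolymeraseRates = field(default_factory=PolymeraseRates)
    rate_scale: float = 1e-4
    rer_retention_minus: float = 1.0
    rer_retention_plus: float = 0.05
    background_rate: float = 2e-5
    n_cells: int = 200
    depth: int = 1_000_000
    sbfi_end_fraction: float = 0.25
    n_sbfi_sites_per_chromosome: int = 25
    acs_length: int = 33

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("origin_efficiency", "rer_retention_minus", "rer_retention_plus",
                     "sbfi_end_fraction", "p_prime"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.origin_efficiency <= 0:
            raise ValueError("origin_efficiency must be in (0, 1]")
        if self.model not in ("model1", "model2"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.priming_mode not in ("gaussian_start", "geometric"):
            raise ValueError(f"unknown priming mode {self.priming_mode!r}")

    @property
    def min_fragment(self) -> int:
        return self.alpha_primer_length + 5

    @property
    def lagging_alpha_fraction(self) -> float:
        return self.alpha_primer_length / self.okazaki_mean

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class Tracts:
    """Disjoint polymerase tracts on one strand of one molecule copy."""

    start: np.ndarray  # int64
    end: np.ndarray  # int64, half-open
    pol: np.ndarray  # int8 index into POL_NAMES
    cls: np.ndarray  # int8 index into CLASS_NAMES


@dataclass
class MoleculeAnnotation:
    """Per-copy, per-strand tract structure of the simulated genomes."""

    genome: Genome
    copies: list[dict[str, dict[str, Tracts]]]  # copy -> chrom -> strand -> tracts

    @property
    def n_copies(self) -> int:
        return len(self.copies)


def _rng_for(config: SimConfig, stream: str) -> np.random.Generator:
    """Substream generator derived from the config seed by stable hashing."""
    return np.random.default_rng([config.seed % (2**31), zlib.crc32(stream.encode())])


# ---------------------------------------------------------------------------
# genome and origins
# ---------------------------------------------------------------------------

def make_genome_and_origins(
    config: SimConfig, outdir: str | Path | None = None
) -> tuple[Genome, OriginSet]:
    """Random genome with planted SbfI sites and evenly spaced origins.

    Exactly ``n_sbfi_sites_per_chromosome`` recognition-site occurrences are
    guaranteed per chromosome (accidental occurrences are scrubbed), origins
    alternate strand, and everything is deterministic under the seed.  When
    ``outdir`` is given, FASTA and BED6 files are written there.
    """
    rng = _rng_for(config, "genome")
    bases = np.array(list("ACGT"))
    lengths: dict[str, int] = {}
    sequence: dict[str, str] = {}
    origin_entries: list[Origin] = []
    motif = RECOGNITION_SEQUENCE
    for ci in range(config.n_chromosomes):
        chrom = f"chrSim{ci + 1}"
        n = config.chromosome_length
        seq = rng.choice(bases, size=n)
        n_ori = config.n_origins_per_chromosome
        anchors = [int(n * (2 * i + 1) / (2 * n_ori)) for i in range(n_ori)]
        for oi, anchor in enumerate(anchors):
            strand = "+" if oi % 2 == 0 else "-"
            origin_entries.append(
                Origin(chrom=chrom, anchor=anchor, strand=strand,
                       name=f"ARS{ci + 1:02d}{oi + 1:02d}")
            )
        # plant restriction sites at jittered regular spacing, away from origins
        n_sites = config.n_sbfi_sites_per_chromosome
        spacing = n // (n_sites + 1)
        site_starts = []
        for si in range(n_sites):
            pos = spacing * (si + 1) + int(rng.integers(-spacing // 4, spacing // 4 + 1))
            pos = int(np.clip(pos, 10, n - len(motif) - 10))
            if any(abs(pos - a) < 400 for a in anchors):
                pos += 400
            site_starts.append(pos)
        site_starts = sorted(set(site_starts))
        for pos in site_starts:
            seq[pos : pos + len(motif)] = list(motif)
        s = "".join(seq)
        # scrub accidental occurrences so planted count == scanned count
        planted = set(site_starts)
        while True:
            found = []
            start = s.find(motif)
            while start != -1:
                found.append(start)
                start = s.find(motif, start + 1)
            extra = [p for p in found if p not in planted]
            if not extra:
                if len(found) != len(planted):  # pragma: no cover - safety net
                    raise RuntimeError("planted restriction site was destroyed")
                break
            s_list = list(s)
            for p in extra:
                s_list[p] = "A" if s_list[p] != "A" else "T"
            s = "".join(s_list)
        lengths[chrom] = n
        sequence[chrom] = s
    genome = Genome(lengths=lengths, sequence=sequence)
    origins = OriginSet(entries=origin_entries)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genome(genome, outdir / "genome.fa")
        write_origins(origins, outdir / "origins.bed", acs_length=config.acs_length)
    return genome, origins


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

def _draw_priming_offset(config: SimConfig, rng: np.random.Generator) -> float:
    if config.priming_mode == "gaussian_start":
        return float(rng.normal(config.alpha_start_mean, config.alpha_start_sd))
    # geometric: priming while ssDNA is exposed, decaying upstream of the axis
    g = float(rng.geometric(config.p_prime) - 1)
    return config.symmetry_axis - g


def _okazaki_lengths(total: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Fragment lengths covering ``total`` bp (last fragment truncated)."""
    if total <= 0:
        return np.empty(0, dtype=np.int64)
    n_est = max(8, int(2.5 * total / config.okazaki_mean) + 8)
    lens = rng.normal(config.okazaki_mean, config.okazaki_sd, size=n_est)
    lens = np.maximum(lens, config.min_fragment).astype(np.int64)
    while lens.sum() < total:  # pragma: no cover - n_est is generous
        more = rng.normal(config.okazaki_mean, config.okazaki_sd, size=n_est)
        lens = np.concatenate([lens, np.maximum(more, config.min_fragment).astype(np.int64)])
    cum = np.cumsum(lens)
    k = int(np.searchsorted(cum, total)) + 1
    lens = lens[:k]
    lens[-1] -= int(cum[k - 1] - total)
    return lens[lens > 0]


class _TractBuilder:
    """Collects tracts for one strand of one copy."""

    def __init__(self) -> None:
        self.start: list[int] = []
        self.end: list[int] = []
        self.pol: list[int] = []
        self.cls: list[int] = []

    def add(self, s: int, e: int, pol: str, cls: str) -> None:
        if e > s:
            self.start.append(s)
            self.end.append(e)
            self.pol.append(POL_NAMES.index(pol))
            self.cls.append(CLASS_NAMES.index(cls))

    def build(self) -> Tracts:
        order = np.argsort(np.array(self.start, dtype=np.int64), kind="stable")
        return Tracts(
            start=np.array(self.start, dtype=np.int64)[order],
            end=np.array(self.end, dtype=np.int64)[order],
            pol=np.array(self.pol, dtype=np.int8)[order],
            cls=np.array(self.cls, dtype=np.int8)[order],
        )


def _leading_rightward(
    b: _TractBuilder, start: int, rb: int, config: SimConfig, rng: np.random.Generator
) -> None:
    """Leading strand of a rightward-moving fork over [start, rb)."""
    ell = config.alpha_primer_length
    if config.model == "model1":
        tract = max(0, int(round(rng.normal(config.delta_tract_mean, config.delta_tract_sd))))
        b.add(start, min(start + ell, rb), "alpha", "leading")
        b.add(min(start + ell, rb), min(start + ell + tract, rb), "delta", "origin-delta-tract")
        b.add(min(start + ell + tract, rb), rb, "epsilon", "leading")
    else:  # model 2: epsilon-extended leading; converging-fork Okazaki fragment
        # nick-translates a delta tract over the displaced 5' primer terminus
        ext = max(0, int(round(rng.normal(config.delta_tract_mean, config.delta_tract_sd))))
        b.add(start, min(start + ext, rb), "delta", "origin-delta-tract")
        if ext < ell:
            b.add(start + ext, min(start + ell, rb), "alpha", "leading")
        b.add(min(start + max(ext, ell), rb), rb, "epsilon", "leading")


def _leading_leftward(
    b: _TractBuilder, lb: int, end: int, config: SimConfig, rng: np.random.Generator
) -> None:
    """Leading strand of a leftward-moving fork over [lb, end) (5' end at high coord)."""
    ell = config.alpha_primer_length
    if config.model == "model1":
        tract = max(0, int(round(rng.normal(config.delta_tract_mean, config.delta_tract_sd))))
        b.add(max(end - ell, lb), end, "alpha", "leading")
        b.add(max(end - ell - tract, lb), max(end - ell, lb), "delta", "origin-delta-tract")
        b.add(lb, max(end - ell - tract, lb), "epsilon", "leading")
    else:
        ext = max(0, int(round(rng.normal(config.delta_tract_mean, config.delta_tract_sd))))
        b.add(max(end - ext, lb), end, "delta", "origin-delta-tract")
        if ext < ell:
            b.add(max(end - ell, lb), end - ext, "alpha", "leading")
        b.add(lb, max(end - max(ext, ell), lb), "epsilon", "leading")


def _lagging_fill(
    b: _TractBuilder,
    lo: int,
    hi: int,
    from_high: bool,
    primer_at_low: bool,
    config: SimConfig,
    rng: np.random.Generator,
) -> None:
    """Tile [lo, hi) with Okazaki fragments.

    ``from_high`` controls which end the origin-proximal (first-made) fragment
    abuts; ``primer_at_low`` places the Pol alpha primer at each fragment's
    low-coordinate end (forward-strand fragments) or high end (reverse).
    """
    total = hi - lo
    lens = _okazaki_lengths(total, config, rng)
    ell = config.alpha_primer_length
    edge = hi if from_high else lo
    for l_frag in lens:
        if from_high:
            s, e = edge - int(l_frag), edge
            edge = s
        else:
            s, e = edge, edge + int(l_frag)
            edge = e
        if primer_at_low:
            split = min(s + ell, e)
            b.add(s, split, "alpha", "lagging-primer")
            b.add(split, e, "delta", "lagging-body")
        else:
            split = max(e - ell, s)
            b.add(split, e, "alpha", "lagging-primer")
            b.add(s, split, "delta", "lagging-body")


def simulate_replication(
    genome: Genome, origins: OriginSet, config: SimConfig
) -> MoleculeAnnotation:
    """Simulate ``n_cells`` genome copies of replication tract structure."""
    rng = _rng_for(config, "replication")
    by_chrom: dict[str, list[Origin]] = {c: [] for c in genome.chromosomes}
    for o in origins:
        by_chrom[o.chrom].append(o)
    copies = []
    for _ in range(config.n_cells):
        copy: dict[str, dict[str, Tracts]] = {}
        for chrom, n in genome.lengths.items():
            oris = sorted(by_chrom[chrom], key=lambda o: o.anchor)
            fired = [o for o in oris if rng.random() < config.origin_efficiency]
            fwd_b, rev_b = _TractBuilder(), _TractBuilder()
            if fired:
                anchors = [o.anchor for o in fired]
                mids = [0] + [
                    (anchors[i] + anchors[i + 1]) // 2 for i in range(len(anchors) - 1)
                ] + [n]
                for i, o in enumerate(fired):
                    lb, rb = mids[i], mids[i + 1]
                    x_down = _draw_priming_offset(config, rng)
                    x_up = 2.0 * config.symmetry_axis - _draw_priming_offset(config, rng)
                    if o.strand == "+":
                        fwd_start = o.anchor + int(round(x_down))
                        rev_end = o.anchor + int(round(x_up))
                    else:
                        fwd_start = o.anchor - int(round(x_up))
                        rev_end = o.anchor - int(round(x_down))
                    fwd_start = int(np.clip(fwd_start, lb, rb))
                    rev_end = int(np.clip(rev_end, lb, rb))
                    # forward strand: converging-fork lagging, then rightward leading
                    _lagging_fill(fwd_b, lb, fwd_start, from_high=True,
                                  primer_at_low=True, config=config, rng=rng)
                    _leading_rightward(fwd_b, fwd_start, rb, config, rng)
                    # reverse strand: leftward leading, then converging-fork lagging
                    _leading_leftward(rev_b, lb, rev_end, config, rng)
                    _lagging_fill(rev_b, rev_end, rb, from_high=False,
                                  primer_at_low=False, config=config, rng=rng)
            copy[chrom] = {"fwd": fwd_b.build(), "rev": rev_b.build()}
        copies.append(copy)
    return MoleculeAnnotation(genome=genome, copies=copies)


def coverage_by_label(annotation: MoleculeAnnotation) -> dict[str, dict[str, np.ndarray]]:
    """Summed per-position copy coverage per (strand, polymerase/class label).

    Returns ``{chrom: {strand: array (n_labels, length)}}`` with the label
    axis ordered as :data:`LABELS`.  Uses difference arrays, so cost is
    linear in the number of tracts plus genome size.
    """
    label_index = {lab: i for i, lab in enumerate(LABELS)}
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, n in annotation.genome.lengths.items():
        out[chrom] = {
            s: np.zeros((len(LABELS), n + 1)) for s in ("fwd", "rev")
        }
    for copy in annotation.copies:
        for chrom, strands in copy.items():
            for strand, tracts in strands.items():
                diff = out[chrom][strand]
                labels = [
                    label_index[(POL_NAMES[p], CLASS_NAMES[c])]
                    for p, c in zip(tracts.pol, tracts.cls)
                ]
                labels = np.asarray(labels, dtype=np.int64)
                np.add.at(diff, (labels, tracts.start), 1.0)
                np.add.at(diff, (labels, tracts.end), -1.0)
    for chrom in out:
        for strand in out[chrom]:
            out[chrom][strand] = np.cumsum(out[chrom][strand], axis=1)[:, :-1]
    return out


# ---------------------------------------------------------------------------
# ribonucleotide incorporation and end sampling
# ---------------------------------------------------------------------------

@dataclass
class SampleSim:
    """One simulated library with full truth labels."""

    spec: SampleSpec
    track: StrandedEndTrack  # complete raw 5'-end track (signal + background + SbfI)
    signal_track: StrandedEndTrack  # ribonucleotide-derived raw 5' ends only
    truth: pd.DataFrame  # chrom, position (rNMP coord), strand, polymerase, tract_class, count
    n_signal: int
    n_background: int
    n_sbfi: int


def _retention(config: SimConfig, rer: str) -> float:
    return config.rer_retention_minus if rer == "RER-" else config.rer_retention_plus


def incorporate_and_sample(
    annotation: MoleculeAnnotation,
    sample: SampleSpec,
    config: SimConfig,
    coverage: dict[str, dict[str, np.ndarray]] | None = None,
) -> SampleSim:
    """Sample one library's 5' ends with truth labels.

    Per nascent position the ribonucleotide weight is
    coverage * rho[pol, allele] * rate_scale * retention; a uniform
    background weight ``n_cells * background_rate`` per strand position and
    SbfI cleavage ends at ``sbfi_end_fraction`` of the library complete the
    sampling distribution, and ``depth`` ends are drawn multinomially using
    a per-sample substream keyed by sample_id.
    """
    if coverage is None:
        coverage = coverage_by_label(annotation)
    rng = _rng_for(config, f"sample:{sample.sample_id}")
    genome = annotation.genome
    variant_pol = VARIANT_TO_POL.get(sample.variant_polymerase)
    retention = _retention(config, sample.rer)
    rho = {
        p: config.rates.rho(p, p == variant_pol) * config.rate_scale
        for p in POL_NAMES
    }
    chroms = genome.chromosomes
    weights = []  # flat blocks: per chrom, per strand: (n_labels, length)
    block_meta = []
    for chrom in chroms:
        n = genome.lengths[chrom]
        for strand in ("fwd", "rev"):
            w = coverage[chrom][strand].copy()
            for li, (pol, _cls) in enumerate(LABELS):
                w[li] *= rho[pol] * retention
            # chromosome-terminal ribonucleotides yield no sequencable end
            if strand == "fwd":
                w[:, n - 1] = 0.0
            else:
                w[:, 0] = 0.0
            weights.append(w.ravel())
            block_meta.append(("signal", chrom, strand, w.shape))
    bg_weight = config.n_cells * config.background_rate
    for chrom in chroms:
        n = genome.lengths[chrom]
        for strand in ("fwd", "rev"):
            weights.append(np.full(n, bg_weight))
            block_meta.append(("background", chrom, strand, (n,)))
    sites = find_sbfi_sites(genome)
    site_ends = sites.predicted_end_positions
    # SbfI cleavage is per genome copy, independent of genotype: the site
    # weight is anchored on the (likewise genotype-independent) background,
    # with sbfi_end_fraction the end fraction in a signal-free library.
    # Signal-rich libraries therefore carry proportionally fewer site ends,
    # exactly as fixed-depth sequencing of a real digest behaves, and SbfI
    # size factors restore every sample to a common per-cell scale.
    w_background = float(
        bg_weight * 2 * sum(genome.lengths[c] for c in chroms)
    )
    if config.sbfi_end_fraction > 0 and site_ends:
        w_sbfi_total = (
            config.sbfi_end_fraction / (1.0 - config.sbfi_end_fraction) * w_background
        )
        per_end = w_sbfi_total / (2 * len(site_ends))
        sbfi_block = np.full(2 * len(site_ends), per_end)
    else:
        sbfi_block = np.zeros(0)
    weights.append(sbfi_block)
    block_meta.append(("sbfi", None, None, (len(sbfi_block),)))
    flat = np.concatenate(weights)
    total = flat.sum()
    if total <= 0:
        counts = np.zeros(len(flat), dtype=np.int64)
    else:
        counts = rng.multinomial(config.depth, flat / total)
    # unpack counts into tracks and the truth table
    track = StrandedEndTrack.zeros(genome)
    signal = StrandedEndTrack.zeros(genome)
    truth_cols: dict[str, list[np.ndarray]] = {
        "chrom": [], "position": [], "strand": [], "polymerase": [],
        "tract_class": [], "count": [],
    }
    n_signal = n_background = n_sbfi = 0
    strand_symbol = {"fwd": "+", "rev": "-"}
    for block, meta in zip(np.split(counts, np.cumsum([len(b) for b in weights]))[:-1], block_meta):
        kind, chrom, strand, shape = meta
        if kind == "signal":
            mat = block.reshape(shape)
            fwd, rev = track.counts[chrom]
            sfwd, srev = signal.counts[chrom]
            for li, (pol, cls) in enumerate(LABELS):
                nz = np.flatnonzero(mat[li])
                if nz.size == 0:
                    continue
                c = mat[li][nz].astype(float)
                if strand == "fwd":
                    fwd[nz + 1] += c
                    sfwd[nz + 1] += c
                else:
                    rev[nz - 1] += c
                    srev[nz - 1] += c
                n_signal += int(c.sum())
                truth_cols["chrom"].append(np.full(nz.size, chrom, dtype=object))
                truth_cols["position"].append(nz)
                truth_cols["strand"].append(
                    np.full(nz.size, strand_symbol[strand], dtype=object)
                )
                truth_cols["polymerase"].append(np.full(nz.size, pol, dtype=object))
                truth_cols["tract_class"].append(np.full(nz.size, cls, dtype=object))
                truth_cols["count"].append(mat[li][nz])
        elif kind == "background":
            fwd, rev = track.counts[chrom]
            arr = fwd if strand == "fwd" else rev
            nz = np.flatnonzero(block)
            arr[nz] += block[nz].astype(float)
            n_background += int(block.sum())
        else:  # sbfi
            for i, k in enumerate(block):
                if k == 0:
                    continue
                chrom_s, fwd_pos, rev_pos = site_ends[i // 2]
                fwd, rev = track.counts[chrom_s]
                if i % 2 == 0:
                    fwd[fwd_pos] += float(k)
                else:
                    rev[rev_pos] += float(k)
                n_sbfi += int(k)
    if truth_cols["position"]:
        truth = pd.DataFrame(
            {k: np.concatenate(v) for k, v in truth_cols.items()}
        )
        truth["position"] = truth["position"].astype(np.int64)
        truth["count"] = truth["count"].astype(np.int64)
    else:
        truth = pd.DataFrame(
            columns=["chrom", "position", "strand", "polymerase", "tract_class", "count"]
        )
    return SampleSim(
        spec=sample,
        track=track,
        signal_track=signal,
        truth=truth,
        n_signal=n_signal,
        n_background=n_background,
        n_sbfi=n_sbfi,
    )


# ---------------------------------------------------------------------------
# panel-level convenience
# ---------------------------------------------------------------------------

def default_panel_specs(variants: tuple[str, ...] = tuple(VARIANT_TO_POL)) -> list[SampleSpec]:
    """RER− / RER+ library pair for each variant replicase strain."""
    specs = []
    for variant in variants:
        short = variant.split("-")[0] + variant.split("-")[1]
        for rer, tag in (("RER-", "rnh201d"), ("RER+", "RNH201")):
            specs.append(
                SampleSpec(
                    sample_id=f"{short}_{tag}",
                    variant_polymerase=variant,
                    rer=rer,
                )
            )
    return specs


@dataclass
class PanelSim:
    """A simulated multi-sample experiment plus shared ground truth."""

    config: SimConfig
    genome: Genome
    origins: OriginSet
    annotation: MoleculeAnnotation
    samples: dict[str, SampleSim]

    def tracks(self) -> dict[str, StrandedEndTrack]:
        return {sid: s.track for sid, s in self.samples.items()}

    def sheet(self) -> pd.DataFrame:
        rows = []
        for sid, s in self.samples.items():
            rows.append(
                {
                    "sample_id": sid,
                    "variant_polymerase": s.spec.variant_polymerase,
                    "pol2_allele": s.spec.pol2_allele,
                    "rer": s.spec.rer,
                    "replicate": s.spec.replicate,
                    "fwd_path": f"{sid}.fwd.bedgraph",
                    "rev_path": f"{sid}.rev.bedgraph",
                }
            )
        return pd.DataFrame(rows)


def simulate_panel(
    config: SimConfig, specs: list[SampleSpec] | None = None
) -> PanelSim:
    """Simulate a full multi-sample experiment (shared replication truth)."""
    if specs is None:
        specs = default_panel_specs()
    genome, origins = make_genome_and_origins(config)
    annotation = simulate_replication(genome, origins, config)
    coverage = coverage_by_label(annotation)
    samples = {
        s.sample_id: incorporate_and_sample(annotation, s, config, coverage=coverage)
        for s in specs
    }
    return PanelSim(config=config, genome=genome, origins=origins,
                    annotation=annotation, samples=samples)


def write_panel(panel: PanelSim, outdir: str | Path) -> None:
    """Write the panel as standard-format pipeline inputs plus truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(panel.genome, outdir / "genome.fa")
    write_origins(panel.origins, outdir / "origins.bed", acs_length=panel.config.acs_length)
    panel.sheet().to_csv(outdir / "samples.tsv", sep="\t", index=False)
    for sid, s in panel.samples.items():
        write_end_track(s.track, outdir / f"{sid}.fwd.bedgraph", outdir / f"{sid}.rev.bedgraph")
        s.truth.to_csv(outdir / f"{sid}.truth.tsv", sep="\t", index=False)
    (outdir / "sim_config.json").write_text(panel.config.to_json())


# ---------------------------------------------------------------------------
# closed-form expectations used as oracles
# ---------------------------------------------------------------------------

def expected_strand_bias(config: SimConfig, variant_polymerase: str) -> float:
    """Closed-form distal-flank r_b for a RER−/RER+ pair of one genotype.

    On the distal flanks the lagging strand is canonical Okazaki synthesis
    (Pol alpha fraction ell/okazaki_mean, rest Pol delta) and the leading
    strand is Pol epsilon; with per-bp ribonucleotide intensity I_c on strand
    class c, retention r−/r+ and uniform background b per bp, the per-bin
    RER−/RER+ ratio is proportional to (I_c r− + b)/(I_c r+ + b), and

        r_b = [(I_lag r− + b)(I_lead r+ + b)] /
              [(I_lag r+ + b)(I_lead r− + b)]

    (normalization constants cancel between the strand classes).
    """
    pol = VARIANT_TO_POL.get(variant_polymerase)
    rho = {p: config.rates.rho(p, p == pol) * config.rate_scale for p in POL_NAMES}
    pf = config.lagging_alpha_fraction
    i_lag = rho["alpha"] * pf + rho["delta"] * (1.0 - pf)
    i_lead = rho["epsilon"]
    b = config.background_rate
    r_minus, r_plus = config.rer_retention_minus, config.rer_retention_plus
    return ((i_lag * r_minus + b) * (i_lead * r_plus + b)) / (
        (i_lag * r_plus + b) * (i_lead * r_minus + b)
    )
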