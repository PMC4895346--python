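"""Synthetic genomes, reads, footprints and chromatin tracks with ground truth.

Every pipeline stage can be exercised without external downloads: a random
genome with planted motif instances of graded affinity, ChIP-seq-like read
5' positions offset by half the fragment length around true sites, DNase
footprint profiles mixing a shifted "typical" shape with flat background,
smooth histone-like enrichment tracks coupled to the planted occupancy,
and conservation/SNP tracks tied to the motif positions.

Planted occupancy follows a configurable function of three latent site
properties — motif affinity (the PWM score of the planted instance),
chromatin accessibility, and a histone-state latent — which allows factor
archetypes to be emulated: affinity-dominated recruitment ("ctcf_like",
"rest_like") versus chromatin-dominated recruitment ("jund_like") where
the motif score carries almost no information about binding strength.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pwm import (HUMAN_BACKGROUND, PWM, PositionFrequencyMatrix, SiteList,
                  encode_sequence, log_odds_from_probabilities)
from .tracks import NumericTrack, TagTrack

HISTONE_MARKS = ("H3K4me2", "H3K4me3", "H4K20me1", "H3K9ac", "H3K27ac",
                 "H3K27me3", "H3K36me3")

#: Archetype weight presets over (affinity, accessibility, histone latent).
ARCHETYPES = {
    "ctcf_like": {"affinity": 3.0, "accessibility": 2.0, "histone": 0.5},
    "jund_like": {"affinity": 0.0, "accessibility": 3.0, "histone": 2.0},
    "rest_like": {"affinity": 3.0, "accessibility": 0.0, "histone": 0.0},
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def default_motif(length: int = 11, consensus_weight: float = 0.85,
                  seed: int = 7) -> PositionFrequencyMatrix:
    """A reproducible information-rich motif for simulations."""
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 4, size=length)
    values = np.full((length, 4), (1 - consensus_weight) / 3)
    values[np.arange(length), consensus] = consensus_weight
    return PositionFrequencyMatrix(values, name="simulated_motif")


def default_footprint_shape(core_bins: int = 100) -> np.ndarray:
    """Double-peak DNase footprint: cut-site peaks flanking a protected core."""
    x = np.linspace(-1, 1, core_bins)    # +/- 1 = +/- 500 bp
    shape = (np.exp(-0.5 * ((x + 0.06) / 0.02) ** 2)
             + np.exp(-0.5 * ((x - 0.06) / 0.02) ** 2)
             + 0.25 * np.exp(-0.5 * (x / 0.3) ** 2) + 0.02)
    shape[np.abs(x) < 0.03] *= 0.15       # protected footprint core
    return shape / shape.sum()


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with ground-truth-friendly defaults."""

    genome_length: int = 700_000
    chrom: str = "chrS"
    gc_fraction: float = 0.41            # human-like base composition
    n_sites: int = 300
    motif: PositionFrequencyMatrix = field(default_factory=default_motif)
    fragment_length: int = 150
    depth: float = 20.0                  # expected reads per site
    read_jitter_sd: float = 10.0
    background_rate: float = 0.1         # background tags / signal tags
    occupancy_model: str = "linear"      # linear | threshold | interaction
    weights: dict = field(
        default_factory=lambda: dict(ARCHETYPES["ctcf_like"]))
    base_occupancy: float = 10.0
    noise_sd: float = 0.1
    footprint_halfwidth: int = 500
    footprint_binsize: int = 10
    footprint_max_shift: int = 50
    footprint_depth: float = 100.0       # expected DNase tags per site
    fraction_atypical: float = 0.3
    track_coupling: float = 0.3          # histone amplitude per unit occupancy
    track_baseline: float = 1.0
    track_noise_sd: float = 0.5
    snp_rate: float = 1 / 300            # SNPs per base, background
    conserved_thinning: float = 0.3      # SNP retention inside motif spans
    seed: int = 0

    @property
    def shift_grid(self) -> np.ndarray:
        step = self.footprint_binsize
        m = self.footprint_max_shift
        return np.arange(-m, m + 1, step)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["motif"] = self.motif.values.tolist()
        out["motif_name"] = self.motif.name
        return out


@dataclass
class SimulatedBundle:
    """Everything one simulated study emits, plus the ground truth."""

    config: SimulationConfig
    seq_by_chrom: dict
    sites: SiteList
    truth: pd.DataFrame
    chip: TagTrack
    dnase: TagTrack
    histone_tracks: dict
    conservation: NumericTrack
    snps: SiteList


def _child(rng: np.random.Generator) -> np.random.Generator:
    return np.random.default_rng(int(rng.integers(0, 2 ** 31)))


def generate_genome(config: SimulationConfig, rng=None):
    """Random genome with planted motif instances at non-overlapping sites.

    Returns ``(seq_by_chrom, sites, truth)``; the truth frame records the
    planted instance's PWM score (log2 odds against the human-like
    background) as the site's intrinsic affinity.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    length = config.genome_length
    if length < 1000:
        raise ValueError("genome length must be at least 1000")
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=probs)
    motif_len = len(config.motif)
    margin = 1600                        # room for the widest feature window
    spacing = 2200
    capacity = (length - 2 * margin) // spacing
    if config.n_sites > capacity:
        raise ValueError(
            f"cannot place {config.n_sites} non-overlapping sites in "
            f"{length} bp (capacity {capacity})")
    slots = margin + spacing * rng.permutation(capacity)[:config.n_sites]
    starts = np.sort(slots + rng.integers(0, spacing - 2 * margin // 2,
                                          size=config.n_sites))
    pwm = log_odds_from_probabilities(config.motif, HUMAN_BACKGROUND)
    motif_probs = config.motif.probabilities
    records = []
    truth_rows = []
    for i, start in enumerate(starts):
        instance = np.array([rng.choice(4, p=motif_probs[j])
                             for j in range(motif_len)])
        affinity = float(pwm.weights[np.arange(motif_len), instance].sum())
        strand = "+" if rng.random() < 0.5 else "-"
        center = int(start) + (motif_len - 1) // 2
        if strand == "+":
            codes[start:start + motif_len] = instance
        else:
            codes[start:start + motif_len] = 3 - instance[::-1]
            center = int(start) + motif_len - 1 - (motif_len - 1) // 2
        site_id = f"site_{i:04d}"
        records.append((config.chrom, center, strand, affinity, site_id))
        truth_rows.append({"id": site_id, "chrom": config.chrom,
                           "center": center, "strand": strand,
                           "affinity": affinity})
    seq = "".join("ACGT"[c] for c in codes)
    sites = SiteList.from_records(records)
    truth = pd.DataFrame(truth_rows).set_index("id")
    return {config.chrom: seq}, sites, truth


def simulate_occupancy(truth: pd.DataFrame, config: SimulationConfig,
                       rng=None) -> pd.DataFrame:
    """Planted occupancy as a function of affinity/accessibility/histone.

    The latent features are z-scored; occupancy is
    ``max(base + g(w . z) + noise, 0)`` with ``g`` the identity (linear),
    a rectifier (threshold), or identity plus an affinity-accessibility
    product term (interaction).  Adds columns accessibility, histone
    latent and occupancy to the truth frame.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = len(truth)
    truth = truth.copy()
    accessibility = rng.normal(size=n)
    histone = 0.7 * accessibility + np.sqrt(1 - 0.7 ** 2) * rng.normal(size=n)
    aff = truth["affinity"].to_numpy()
    z_aff = (aff - aff.mean()) / (aff.std() if aff.std() > 0 else 1.0)
    w = config.weights
    eta = (w.get("affinity", 0.0) * z_aff
           + w.get("accessibility", 0.0) * accessibility
           + w.get("histone", 0.0) * histone)
    if config.occupancy_model == "linear":
        g = eta
    elif config.occupancy_model == "threshold":
        g = np.where(eta > 0, eta, 0.0)
    elif config.occupancy_model == "interaction":
        g = eta + 0.5 * z_aff * accessibility
    else:
        raise ValueError(f"unknown occupancy model {config.occupancy_model!r}")
    noise = rng.normal(scale=config.noise_sd, size=n)
    occupancy = np.clip(config.base_occupancy + g + noise, 0.0, None)
    truth["accessibility"] = accessibility
    truth["histone_latent"] = histone
    truth["occupancy"] = occupancy
    return truth


def simulate_reads(sites: SiteList, occupancy: np.ndarray,
                   fragment_length: int, depth: float,
                   genome_length: int, chrom: str = "chrS",
                   jitter_sd: float = 10.0, background_rate: float = 0.1,
                   seed: int = 0, name: str = "chip") -> TagTrack:
    """ChIP-seq-like 5' tag positions around sites.

    Each site draws ``Poisson(depth * occupancy / mean(occupancy))``
    fragments; a fragment contributes a plus-strand 5' end near
    ``center - fragment_length/2`` and a minus-strand 5' end near
    ``center + fragment_length/2``, each with Gaussian jitter.  Uniform
    background tags are added at ``background_rate`` times the signal.
    """
    if fragment_length <= 0:
        raise ValueError("fragment length must be positive")
    rng = np.random.default_rng(seed)
    occupancy = np.asarray(occupancy, dtype=float)
    mean = occupancy.mean() if occupancy.size and occupancy.mean() > 0 else 1.0
    lam = depth * occupancy / mean
    records = []
    half = fragment_length / 2.0
    total_signal = 0
    for site, site_lam in zip(sites, lam):
        nfrag = rng.poisson(site_lam)
        total_signal += nfrag
        if nfrag == 0:
            continue
        eps_p = rng.normal(scale=jitter_sd, size=nfrag)
        eps_m = rng.normal(scale=jitter_sd, size=nfrag)
        plus = np.clip(np.rint(site.center - half + eps_p), 0,
                       genome_length - 1).astype(int)
        minus = np.clip(np.rint(site.center + half + eps_m), 0,
                        genome_length - 1).astype(int)
        records.extend((chrom, int(p), "+") for p in plus)
        records.extend((chrom, int(m), "-") for m in minus)
    n_bg = rng.poisson(background_rate * max(total_signal, 1) * 2)
    bg_pos = rng.integers(0, genome_length, size=n_bg)
    bg_strand = rng.random(size=n_bg) < 0.5
    records.extend((chrom, int(p), "+" if s else "-")
                   for p, s in zip(bg_pos, bg_strand))
    return TagTrack.from_positions(records, name=name)


def simulate_footprints(sites: SiteList, config: SimulationConfig,
                        accessibility: np.ndarray | None = None,
                        typical_shape: np.ndarray | None = None,
                        seed: int = 0):
    """DNase-like tags: typical sites carry a shifted footprint shape.

    A typical site draws tag offsets from the footprint shape displaced by
    a shift sampled from the configured grid; atypical sites draw uniform
    offsets.  Per-site depth scales with accessibility, so windowed DNase
    counts are informative about it.  Returns ``(track, truth_frame)``
    where the truth records the class and the *re-centering* shift (the
    correction the partitioning should report, i.e. minus the planted
    displacement).
    """
    rng = np.random.default_rng(seed)
    halfwidth = config.footprint_halfwidth
    binsize = config.footprint_binsize
    core_bins = (2 * halfwidth) // binsize
    shape = (np.asarray(typical_shape, dtype=float)
             if typical_shape is not None
             else default_footprint_shape(core_bins))
    if len(shape) != core_bins:
        raise ValueError(f"shape vector must have {core_bins} bins")
    shape = shape / shape.sum()
    per_base = np.repeat(shape / binsize, binsize)
    n = len(sites)
    if accessibility is None:
        rel_depth = np.ones(n)
    else:
        rel = np.exp(0.5 * np.asarray(accessibility, dtype=float))
        rel_depth = rel / rel.mean()
    typical = rng.random(n) >= config.fraction_atypical
    grid = config.shift_grid
    shifts = rng.choice(grid, size=n)
    records = []
    rows = []
    offsets_domain = np.arange(-halfwidth, halfwidth)
    for i, site in enumerate(sites):
        ntags = rng.poisson(config.footprint_depth * rel_depth[i])
        if typical[i]:
            offs = rng.choice(offsets_domain, size=ntags, p=per_base)
            offs = offs + shifts[i]
        else:
            offs = rng.integers(-halfwidth - config.footprint_max_shift,
                                halfwidth + config.footprint_max_shift,
                                size=ntags)
        strands = rng.random(ntags) < 0.5
        records.extend((site.chrom, int(site.center + o), "+" if s else "-")
                       for o, s in zip(offs, strands))
        rows.append({"id": site.id, "footprint_class":
                     "typical" if typical[i] else "atypical",
                     "footprint_shift": -int(shifts[i]) if typical[i] else 0})
    track = TagTrack.from_positions(records, name="dnase")
    return track, pd.DataFrame(rows).set_index("id")


def simulate_tracks(sites: SiteList, occupancy: np.ndarray,
                    config: SimulationConfig, rng=None):
    """Histone-like smooth tracks, conservation, and SNP positions.

    Each histone mark is a sum of Gaussian bumps at site centers with
    amplitude ``a * occupancy + b + noise`` on a 10-bp binned genome;
    conservation is elevated inside motif spans; SNPs are a Poisson
    process thinned inside the conserved spans.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    binsize = 10
    nbins = config.genome_length // binsize
    bin_centers = np.arange(nbins) * binsize + binsize // 2
    occupancy = np.asarray(occupancy, dtype=float)
    occ_rel = occupancy / (occupancy.mean() if occupancy.mean() > 0 else 1.0)
    centers = sites.centers
    bw = 300.0
    histone_tracks = {}
    for m, mark in enumerate(HISTONE_MARKS):
        mark_rng = _child(rng)
        values = np.full(nbins, config.track_baseline)
        amp = (config.track_coupling * occ_rel
               + mark_rng.normal(scale=config.track_noise_sd,
                                 size=len(centers)))
        for c, a in zip(centers, amp):
            lo = max(0, int((c - 4 * bw) // binsize))
            hi = min(nbins, int((c + 4 * bw) // binsize) + 1)
            x = bin_centers[lo:hi]
            values[lo:hi] += a * np.exp(-0.5 * ((x - c) / bw) ** 2)
        values += mark_rng.normal(scale=0.05, size=nbins)
        values = np.clip(values, 0.0, None)
        intervals = [(config.chrom, int(b * binsize), int((b + 1) * binsize),
                      float(values[b])) for b in range(nbins)]
        histone_tracks[mark] = NumericTrack.from_intervals(
            intervals, name=mark)
    # conservation: elevated in the +/-10 bp motif span around each center
    cons = np.full(nbins, 0.05)
    conserved = np.zeros(config.genome_length, dtype=bool)
    for c in centers:
        lo, hi = max(0, c - 10), min(config.genome_length, c + 11)
        conserved[lo:hi] = True
        cons[lo // binsize: (hi - 1) // binsize + 1] = 0.9
    cons_rng = _child(rng)
    cons = np.clip(cons + cons_rng.normal(scale=0.02, size=nbins), 0.0, 1.0)
    conservation = NumericTrack.from_intervals(
        [(config.chrom, int(b * binsize), int((b + 1) * binsize),
          float(cons[b])) for b in range(nbins)], name="conservation")
    snp_rng = _child(rng)
    n_snp = snp_rng.poisson(config.snp_rate * config.genome_length)
    pos = np.sort(snp_rng.integers(0, config.genome_length, size=n_snp))
    keep = np.where(conserved[pos],
                    snp_rng.random(n_snp) < config.conserved_thinning, True)
    pos = np.unique(pos[keep])
    snps = SiteList(pd.DataFrame({
        "chrom": config.chrom, "center": pos, "strand": ".",
        "score": 0.0, "id": [f"snp_{i}" for i in range(len(pos))]}))
    return histone_tracks, conservation, snps


def generate_bundle(config: SimulationConfig) -> SimulatedBundle:
    """Run the full generative model at the configured seed."""
    rng = np.random.default_rng(config.seed)
    seq_by_chrom, sites, truth = generate_genome(config, _child(rng))
    truth = simulate_occupancy(truth, config, _child(rng))
    chip = simulate_reads(
        sites, truth["occupancy"].to_numpy(), config.fragment_length,
        config.depth, config.genome_length, chrom=config.chrom,
        jitter_sd=config.read_jitter_sd,
        background_rate=config.background_rate,
        seed=int(_child(rng).integers(0, 2 ** 31)), name="chip")
    dnase, fp_truth = simulate_footprints(
        sites, config, accessibility=truth["accessibility"].to_numpy(),
        seed=int(_child(rng).integers(0, 2 ** 31)))
    truth = truth.join(fp_truth)
    histone_tracks, conservation, snps = simulate_tracks(
        sites, truth["occupancy"].to_numpy(), config, _child(rng))
    return SimulatedBundle(config=config, seq_by_chrom=seq_by_chrom,
                           sites=sites, truth=truth, chip=chip, dnase=dnase,
                           histone_tracks=histone_tracks,
                           conservation=conservation, snps=snps)


def write_bundle(bundle: SimulatedBundle, outdir):
    """Write every artifact of a simulated study as plain-text files."""
    import json
    from pathlib import Path

    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_fasta(bundle.seq_by_chrom, outdir / "genome.fa")
    tio.write_sites_bed(bundle.sites, outdir / "sites.bed")
    tio.write_tag_track(bundle.chip, outdir / "tags_chip.tsv")
    tio.write_tag_track(bundle.dnase, outdir / "tags_dnase.tsv")
    for mark, track in bundle.histone_tracks.items():
        tio.write_bedgraph(track, outdir / f"track_{mark}.bedGraph")
    tio.write_bedgraph(bundle.conservation, outdir / "track_conservation.bedGraph")
    tio.write_snp_bed(bundle.snps, outdir / "snps.bed")
    bundle.truth.to_csv(outdir / "truth.tsv", sep="\t")
    with open(outdir / "config.json", "w") as fh:
        json.dump(bundle.config.to_dict(), fh, indent=2)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
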