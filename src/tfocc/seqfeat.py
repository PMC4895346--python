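"""Sequence-intrinsic features around binding-site centers.

Three feature families: oligonucleotide (k-mer) compositions with an
upstream/downstream split, G+C content, and ten dinucleotide structural
scales averaged over the 20 dinucleotide steps spanning the central
+/- 10 bp.  Windows are defined around a single-base center; bases or
k-mers containing N are excluded from both numerator and denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]

SCALE_NAMES = (
    "a_philicity",
    "z_dna_stability_energy",
    "duplex_disrupt_energy",
    "duplex_stability_free_energy",
    "stacking_energy",
    "dna_denaturation",
    "b_dna_twist",
    "protein_dna_twist",
    "propeller_twist",
    "bending_stiffness",
)


@dataclass(frozen=True)
class StructuralScale:
    """A named dinucleotide property table (16 values)."""

    name: str
    values: dict

    def __post_init__(self):
        if set(self.values) != set(DINUCLEOTIDES):
            raise ValueError("scale must define all 16 dinucleotides")


def load_scales(path=None) -> dict:
    """Load structural scales from a TSV (scale, dinucleotide, value).

    Defaults to the packaged literature-derived table.
    """
    if path is None:
        source = resources.files("tfocc.data") / "dinucleotide_scales.tsv"
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", comment="#")
    else:
        table = pd.read_csv(path, sep="\t", comment="#")
    scales = {}
    for name, sub in table.groupby("scale"):
        scales[name] = StructuralScale(
            name, dict(zip(sub["dinucleotide"], sub["value"])))
    return scales


def _window(seq: str, center: int, halfwidth: int) -> str:
    lo = max(0, center - halfwidth)
    hi = min(len(seq), center + halfwidth + 1)
    return seq[lo:hi].upper()


def _kmer_frequencies(segment: str, k: int) -> dict:
    """Relative frequencies of all k-mers in a segment; N-containing excluded."""
    counts = {"".join(p): 0 for p in itertools.product("ACGT", repeat=k)}
    total = 0
    for i in range(len(segment) - k + 1):
        kmer = segment[i:i + k]
        if kmer in counts:
            counts[kmer] += 1
            total += 1
    if total == 0:
        return {kmer: np.nan for kmer in counts}
    return {kmer: c / total for kmer, c in counts.items()}


def kmer_composition(seq: str, center: int, halfwidth: int = 100,
                     kmax: int = 5) -> pd.Series:
    """k-mer composition features for k = 1..kmax in three blocks.

    The +/- halfwidth window is split at the center base: the upstream
    block covers ``[center - halfwidth, center)``, the downstream block
    ``(center, center + halfwidth]``, and the full block the whole window.
    Frequencies within each (block, k) sum to 1.  With the default
    ``kmax = 5`` this yields 3 * (4 + 16 + 64 + 256 + 1024) = 4032
    features.
    """
    if not 1 <= kmax <= 5:
        raise ValueError("kmax must be in 1..5")
    lo = max(0, center - halfwidth)
    hi = min(len(seq), center + halfwidth + 1)
    full = seq[lo:hi].upper()
    up = seq[lo:center].upper()
    down = seq[center + 1:hi].upper()
    features = {}
    for block, segment in (("up", up), ("down", down), ("full", full)):
        for k in range(1, kmax + 1):
            for kmer, freq in _kmer_frequencies(segment, k).items():
                features[f"{block}_k{k}_{kmer}"] = freq
    return pd.Series(features)


def gc_content(seq: str, center: int, halfwidth: int = 100) -> float:
    """Fraction (G+C)/(A+C+G+T) in the window; N ignored; all-N -> nan."""
    window = _window(seq, center, halfwidth)
    gc = sum(window.count(b) for b in "GC")
    acgt = sum(window.count(b) for b in "ACGT")
    return gc / acgt if acgt else float("nan")


def structural_score(seq: str, center: int, scale: StructuralScale,
                     halfwidth: int = 10) -> float:
    """Mean scale value over the dinucleotide steps spanning the center.

    Step ``i`` covers bases ``(center - halfwidth + i,
    center - halfwidth + i + 1)`` for ``i = 0 .. 2*halfwidth - 1``
    (20 steps at the default halfwidth).  Steps containing N or falling
    outside the sequence are excluded; if none is valid, nan.
    """
    values = []
    for i in range(2 * halfwidth):
        start = center - halfwidth + i
        if start < 0 or start + 2 > len(seq):
            continue
        dinuc = seq[start:start + 2].upper()
        if dinuc in scale.values:
            values.append(scale.values[dinuc])
    return float(np.mean(values)) if values else float("nan")


def annotate_sequence_features(seq_by_chrom: dict, sites,
                               halfwidth: int = 100,
                               scales: dict | None = None,
                               include_kmers: bool = False,
                               kmax: int = 5) -> pd.DataFrame:
    """Sequence feature block for a site list.

    Emits G+C content and the ten structural scores by default; the full
    k-mer composition (4032 columns at kmax = 5) only on request, since
    the compact G+C summary is normally used in its place.
    """
    scales = scales if scales is not None else load_scales()
    rows = []
    for site in sites:
        seq = seq_by_chrom[site.chrom]
        row = {"id": site.id, "gc_content": gc_content(seq, site.center,
                                                       halfwidth)}
        for name, scale in scales.items():
            row[name] = structural_score(seq, site.center, scale)
        if include_kmers:
            row.update(kmer_composition(seq, site.center, halfwidth,
                                        kmax).to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")
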