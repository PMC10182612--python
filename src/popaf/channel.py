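"""Pileup-tensor rendering with a logarithmic allele-frequency channel.

Reads overlapping a variant candidate are rendered as a reads x positions x
channels integer tensor.  Channels 0-5 are simplified stand-ins for the usual
read-level channels (bases, base quality, mapping quality, strand, supports
variant, differs from reference) with documented linear scalings; channel 6
encodes the matched population allele frequency of each read's allele with a
logarithmic intensity transform, so that resolution is concentrated on
low-frequency alleles:

    intensity(af) = round(max_intensity * max(0, 1 - log10(af) / log10(af_floor)))

which maps ``af_floor -> 0`` and ``1 -> max_intensity`` exactly and is
monotone in between.  The same read can receive different intensities in
different candidates' pileups, because its allele at each candidate differs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .matching import AlleleFrequencyDict, annotate_reads, supported_allele
from .model import AlignedRead, GenomicInterval, ReferenceSequence, VariantRecord

CHANNEL_NAMES = (
    "base",
    "base_quality",
    "mapping_quality",
    "strand",
    "supports_variant",
    "differs_from_ref",
    "allele_frequency",
)

_BASE_INTENSITY = {"A": 60, "C": 120, "G": 180, "T": 240}
_MAX_BASEQ = 40
_MAX_MAPQ = 60
_STRAND_FWD = 70
_STRAND_REV = 240


@dataclass(frozen=True)
class TransformParams:
    """Parameters of the logarithmic AF-to-intensity transform.

    ``af_floor`` is the frequency mapped to intensity 0 (default 1e-4, below
    a single allele in a ~5,000-haplotype panel); ``max_intensity`` is the
    intensity of frequency 1.
    """

    af_floor: float = 1e-4
    max_intensity: int = 254

    def __post_init__(self) -> None:
        if not (0.0 < self.af_floor < 1.0):
            raise ValueError("af_floor must lie in (0, 1)")
        if self.max_intensity < 1:
            raise ValueError("max_intensity must be >= 1")


@dataclass
class PileupTensor:
    """reads x positions x channels intensity tensor for one candidate."""

    data: np.ndarray  # shape (n_reads, window length, 7), ints in [0, max]
    window: GenomicInterval
    read_names: tuple[str, ...]
    channel_names: tuple[str, ...] = CHANNEL_NAMES

    def channel(self, name_or_index) -> np.ndarray:
        idx = (self.channel_names.index(name_or_index)
               if isinstance(name_or_index, str) else name_or_index)
        return self.data[:, :, idx]

    def to_tsv(self, directory) -> list[str]:
        """One TSV per channel (rows = reads, columns = window positions)."""
        import pandas as pd
        from pathlib import Path

        paths = []
        cols = list(range(self.window.start, self.window.end))
        for i, name in enumerate(self.channel_names):
            path = Path(directory) / f"channel_{i}_{name}.tsv"
            pd.DataFrame(
                self.data[:, :, i], index=list(self.read_names), columns=cols
            ).to_csv(path, sep="\t")
            paths.append(str(path))
        return paths

    def to_png(self, path) -> None:
        """Optional heatmap rendering of all channels (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        n = len(self.channel_names)
        fig, axes = plt.subplots(1, n, figsize=(3 * n, 4), squeeze=False)
        for i, (ax, name) in enumerate(zip(axes[0], self.channel_names)):
            ax.imshow(self.data[:, :, i], cmap="viridis", vmin=0,
                      vmax=self.data.max() or 1, aspect="auto",
                      interpolation="nearest")
            ax.set_title(name, fontsize=8)
            ax.set_xticks([])
            ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def transform_af(af: float, params: TransformParams = TransformParams()) -> int:
    """Map an allele frequency in [0, 1] to an integer pileup intensity."""
    if not (0.0 <= af <= 1.0):
        raise ValueError(f"allele frequency {af} outside [0, 1]")
    if af <= params.af_floor:
        return 0
    scaled = 1.0 - math.log10(af) / math.log10(params.af_floor)
    if scaled <= 0.0:
        return 0
    # round half away from zero for reproducibility across platforms
    return int(params.max_intensity * scaled + 0.5)


def _sorted_covering(
    reads: Sequence[AlignedRead], candidate: VariantRecord
) -> list[AlignedRead]:
    keep = [r for r in reads if supported_allele(r, candidate) is not None]
    return sorted(keep, key=lambda r: (r.start0, r.name))


def render_af_channel(
    reads: Sequence[AlignedRead],
    candidate: VariantRecord,
    af_dict: AlleleFrequencyDict,
    params: TransformParams = TransformParams(),
    window: Optional[GenomicInterval] = None,
) -> np.ndarray:
    """The AF channel alone: one uniformly-coloured row per covering read.

    Row ``i`` carries ``transform_af`` of read ``i``'s allele frequency at
    the candidate, over the columns the read spans; other columns are 0.
    Reads are ordered by (start, name).
    """
    window = window or candidate.span
    ordered = _sorted_covering(reads, candidate)
    freqs = annotate_reads(ordered, candidate, af_dict)
    mat = np.zeros((len(ordered), len(window)), dtype=np.int64)
    for i, read in enumerate(ordered):
        lo = max(read.start0, window.start)
        hi = min(read.end0, window.end)
        if lo < hi:
            mat[i, lo - window.start:hi - window.start] = transform_af(
                freqs[read.name], params
            )
    return mat


def _aligned_bases(read: AlignedRead) -> dict[int, tuple[str, int]]:
    """reference position -> (base, quality) for M columns of one read."""
    out: dict[int, tuple[str, int]] = {}
    rpos, qpos = read.start0, 0
    for op, n in read.ops:
        if op == "M":
            for k in range(n):
                out[rpos + k] = (read.bases[qpos + k], read.base_quals[qpos + k])
            rpos += n
            qpos += n
        elif op == "I":
            qpos += n
        else:  # D
            rpos += n
    return out


def render_pileup(
    reads: Sequence[AlignedRead],
    reference: ReferenceSequence,
    candidate: VariantRecord,
    window: GenomicInterval,
    af_dict: AlleleFrequencyDict,
    params: TransformParams = TransformParams(),
) -> PileupTensor:
    """Render the full 7-channel pileup tensor over a window."""
    if not window.contains(candidate.span):
        raise ValueError("window must contain the candidate span")
    ref_seq = reference.fetch(window)
    ordered = _sorted_covering(reads, candidate)
    n_rows, n_cols = len(ordered), len(window)
    data = np.zeros((n_rows, n_cols, len(CHANNEL_NAMES)), dtype=np.int64)
    max_i = params.max_intensity
    for i, read in enumerate(ordered):
        bases = _aligned_bases(read)
        supports = supported_allele(read, candidate) in candidate.alts
        for rpos, (base, qual) in bases.items():
            if not (window.start <= rpos < window.end):
                continue
            c = rpos - window.start
            data[i, c, 0] = _BASE_INTENSITY.get(base, 0)
            data[i, c, 1] = int(min(qual, _MAX_BASEQ) / _MAX_BASEQ * max_i + 0.5)
            data[i, c, 2] = int(min(read.mapq, _MAX_MAPQ) / _MAX_MAPQ * max_i + 0.5)
            data[i, c, 3] = _STRAND_FWD if read.strand == "+" else _STRAND_REV
            data[i, c, 4] = max_i if supports else 0
            data[i, c, 5] = max_i if base != ref_seq[c] else 0
    data[:, :, 6] = render_af_channel(reads, candidate, af_dict, params, window)
    return PileupTensor(
        data=data,
        window=window,
        read_names=tuple(r.name for r in ordered),
    )
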