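"""Site-aligned occupancy profiles: strand-aware window extraction around
feature anchors (TSSs, ATGs, called nucleosome positions), cumulative
summation across features and per-window average normalisation, plus the
per-feature matrix used for clustering.

Offsets are measured in each feature's 5′→3′ direction: for a − strand
feature the genomic window is reversed so positive offsets always point
into the gene body.  Window bins that fall off the chromosome contribute
zero and set a per-feature truncation flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nucparticle.track import BinnedTrack

DEFAULT_HALF_WIDTH = 1200
DEFAULT_CLUSTER_WINDOW = (0, 1500)


class DegenerateProfileError(ValueError):
    """Cumulative profile summed to zero everywhere; normalisation undefined."""


@dataclass(frozen=True)
class FeatureAnchor:
    id: str
    chrom: str
    anchor_pos: int  # 0-based bp
    strand: str

    def __post_init__(self) -> None:
        if self.anchor_pos < 0:
            raise ValueError(f"{self.id}: anchor_pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-' (got {self.strand!r})")


@dataclass
class SiteProfile:
    """Cumulative feature-aligned profile over −W…+W bp.

    ``normalised`` is ``cumulative`` divided by its window mean, so it
    averages to exactly 1 over the window.
    """

    offsets: np.ndarray  # bp, on the bin grid
    cumulative: np.ndarray
    normalised: np.ndarray
    n_features: int
    n_truncated: int = 0


@dataclass
class ProfileMatrix:
    ids: list[str]
    offsets: np.ndarray  # bp offsets of the columns (5'->3')
    values: np.ndarray  # n_features x n_bins
    truncated: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.offsets)):
            raise ValueError("ProfileMatrix shape does not match ids/offsets")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.offsets)

    def row(self, feature_id: str) -> np.ndarray:
        return self.values[self.ids.index(feature_id)]

    def column_at(self, offset_bp: int) -> np.ndarray:
        """Per-feature values at the bin containing the given offset."""
        j = int(np.argmin(np.abs(self.offsets - offset_bp)))
        return self.values[:, j]

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            ids=[str(i) for i in df.index],
            offsets=np.asarray([int(c) for c in df.columns]),
            values=df.to_numpy(dtype=float),
        )


def _window_bins(
    track: BinnedTrack, anchor: FeatureAnchor, lo_bin: int, hi_bin: int
) -> tuple[np.ndarray, bool]:
    """Values at bin offsets lo_bin..hi_bin (inclusive) in the feature's
    5'->3' direction; off-chromosome bins are zero-filled."""
    b = anchor.anchor_pos // track.bin_width
    rel = np.arange(lo_bin, hi_bin + 1)
    idx = b + rel if anchor.strand == "+" else b - rel
    valid = (idx >= 0) & (idx < track.n_bins)
    out = np.zeros(rel.size)
    out[valid] = track.values[idx[valid]]
    return out, bool(not valid.all())


def extract_window(
    track: BinnedTrack, anchor: FeatureAnchor, half_width: int = DEFAULT_HALF_WIDTH
) -> tuple[np.ndarray, bool]:
    """Track values at offsets −W…+W around the anchor, strand-aware.

    Returns the value vector and a truncation flag (True when part of the
    window fell off the chromosome and was zero-filled).
    """
    k = half_width // track.bin_width
    return _window_bins(track, anchor, -k, k)


def cumulative_profile(
    tracks: Mapping[str, BinnedTrack],
    features: Sequence[FeatureAnchor],
    half_width: int = DEFAULT_HALF_WIDTH,
) -> SiteProfile:
    """Sum strand-aware windows over all features and normalise to the
    window-average frequency."""
    if not features:
        raise ValueError("cumulative_profile requires at least one feature")
    bin_width = next(iter(tracks.values())).bin_width
    k = half_width // bin_width
    cumulative = np.zeros(2 * k + 1)
    n_truncated = 0
    for anchor in features:
        if anchor.chrom not in tracks:
            raise KeyError(
                f"feature {anchor.id!r}: chromosome {anchor.chrom!r} absent from tracks"
            )
        vals, truncated = extract_window(tracks[anchor.chrom], anchor, half_width)
        cumulative += vals
        n_truncated += truncated
    if cumulative.sum() == 0:
        raise DegenerateProfileError(
            "cumulative profile is zero everywhere; normalisation undefined"
        )
    offsets = np.arange(-k, k + 1) * bin_width
    normalised = cumulative / cumulative.mean()
    return SiteProfile(
        offsets=offsets,
        cumulative=cumulative,
        normalised=normalised,
        n_features=len(features),
        n_truncated=n_truncated,
    )


def profile_matrix(
    tracks: Mapping[str, BinnedTrack],
    features: Sequence[FeatureAnchor],
    window: tuple[int, int] = DEFAULT_CLUSTER_WINDOW,
) -> ProfileMatrix:
    """Per-feature window matrix (no normalisation), rows in input order.

    ``window`` is (start_offset_bp, end_offset_bp) in the feature's 5'->3'
    direction, half-open on the right; the default (0, 1500) covers the
    coding-region nucleosome array downstream of the TSS as 150 bins.
    """
    if not features:
        raise ValueError("profile_matrix requires at least one feature")
    bin_width = next(iter(tracks.values())).bin_width
    lo_bin = window[0] // bin_width
    hi_bin = window[1] // bin_width - 1
    if hi_bin < lo_bin:
        raise ValueError(f"empty window {window}")
    rows = []
    truncated_flags = []
    for anchor in features:
        if anchor.chrom not in tracks:
            raise KeyError(
                f"feature {anchor.id!r}: chromosome {anchor.chrom!r} absent from tracks"
            )
        vals, truncated = _window_bins(tracks[anchor.chrom], anchor, lo_bin, hi_bin)
        rows.append(vals)
        truncated_flags.append(truncated)
    offsets = np.arange(lo_bin, hi_bin + 1) * bin_width
    return ProfileMatrix(
        ids=[f.id for f in features],
        offsets=offsets,
        values=np.vstack(rows),
        truncated=truncated_flags,
    )


def write_profile(profile: SiteProfile, path: str | Path) -> None:
    """Two-column TSV: offset (bp), normalised cumulative value."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("offset\tnormalised\n")
        for o, v in zip(profile.offsets, profile.normalised):
            fh.write(f"{o}\t{v:.6f}\n")


def read_features(path: str | Path) -> list[FeatureAnchor]:
    """Tab-separated feature anchors: id, chrom, 0-based anchor position, strand.

    For anchors from 1-based annotation, subtract 1 from the position
    before writing the file (see :func:`anchor_from_one_based`).
    """
    out: list[FeatureAnchor] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated columns")
            fid, chrom, pos, strand = parts
            out.append(FeatureAnchor(id=fid, chrom=chrom, anchor_pos=int(pos), strand=strand))
    return out


def write_features(features: Sequence[FeatureAnchor], path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for f in features:
            fh.write(f"{f.id}\t{f.chrom}\t{f.anchor_pos}\t{f.strand}\n")


def anchor_from_one_based(
    feature_id: str, chrom: str, pos_1based: int, strand: str
) -> FeatureAnchor:
    """Converter for 1-based annotation coordinates."""
    return FeatureAnchor(id=feature_id, chrom=chrom, anchor_pos=pos_1based - 1, strand=strand)
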