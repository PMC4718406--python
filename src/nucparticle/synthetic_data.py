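"""Ground-truthed synthetic chromatin and MNase digestion simulator.

The generative model plants, at each transcription start site, a
nucleosome-depleted region (NDR) immediately upstream and a phased
nucleosomal array downstream: the +1 nucleosome center sits
``plus_one_offset`` bp into the gene, subsequent centers follow at the
nucleosome repeat length, and one −1 nucleosome sits upstream of the NDR.
Sequencing a digest is emulated per nucleosome: a Poisson number of
protected fragments, each centered on the nucleosome with Gaussian
positional jitter (fuzziness) and a Gaussian fragment length whose mean
shifts downward with heavier digestion.  A uniform background models
sub-nucleosomal and spurious fragments.  A depleted condition scales
occupancy down and fuzziness up, emulating a chromatin-assembly mutant.

Fragments are emitted as proper SAM read pairs (both mates, symmetric
±TLEN) so the simulator's output feeds the ingest module unchanged, and
the planted centers are kept as a ground-truth table for recovery scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
from scipy.stats import norm

from nucparticle.peakcall import PeakCall
from nucparticle.sam_ingest import SizeClassSpec
from nucparticle.site_profile import FeatureAnchor

logger = logging.getLogger(__name__)

READ_LENGTH = 50
FRAGMENT_MIN, FRAGMENT_MAX = 50, 400


@dataclass(frozen=True)
class DigestionSpec:
    """MNase digestion level and the fragment-length distribution it yields."""

    level: str
    fragment_mean: float
    fragment_sd: float = 12.0

    def __post_init__(self) -> None:
        if self.fragment_mean <= 0 or self.fragment_sd < 0:
            raise ValueError("fragment_mean must be > 0 and fragment_sd >= 0")


LOW_DIGESTION = DigestionSpec(level="low", fragment_mean=165.0)
HIGH_DIGESTION = DigestionSpec(level="high", fragment_mean=150.0)


@dataclass(frozen=True)
class ConditionSpec:
    """Strain condition: wild-type, or depleted (lower occupancy, fuzzier)."""

    label: str
    occupancy_scale: float = 1.0
    fuzziness_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.occupancy_scale < 0 or self.fuzziness_scale <= 0:
            raise ValueError("scales must be positive (occupancy_scale may be 0)")


WILDTYPE = ConditionSpec(label="wildtype")
DEPLETED = ConditionSpec(label="depleted", occupancy_scale=0.7, fuzziness_scale=2.0)


@dataclass(frozen=True)
class Nucleosome:
    """One planted nucleosome: ground truth for recovery scoring."""

    feature_id: str
    chrom: str
    center: int  # 0-based bp
    index_in_array: int  # -1 for the upstream nucleosome, 1..n downstream


@dataclass
class ChromatinModel:
    """Deterministic ground truth: planted nucleosome centers plus the
    occupancy/fuzziness/digestion parameters of the genome."""

    chrom_lengths: dict[str, int]
    features: list[FeatureAnchor]
    nucleosomes: list[Nucleosome]
    ndr_width: int = 150
    plus_one_offset: int = 60
    repeat_length: int = 154
    n_nucleosomes_per_array: int = 10
    occupancy: float = 0.9
    fuzziness_sd: float = 10.0
    background_rate: float = 2.0  # fragments per kb

    def centers_by_chrom(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {c: [] for c in self.chrom_lengths}
        for nuc in self.nucleosomes:
            out[nuc.chrom].append(nuc.center)
        return {c: np.asarray(sorted(v), dtype=np.int64) for c, v in out.items()}


def make_synthetic_genome(
    n_genes: int = 20,
    n_chroms: int = 2,
    gene_spacing: int = 4000,
    margin: int = 3000,
) -> tuple[dict[str, int], list[FeatureAnchor]]:
    """Lay out a compact synthetic genome with evenly spaced TSSs.

    Genes alternate strand so strand-aware code paths are exercised;
    spacing keeps each TSS's ±1,200 bp window clear of its neighbours.
    """
    if n_genes < 1:
        raise ValueError("need at least one gene")
    per_chrom = [n_genes // n_chroms + (i < n_genes % n_chroms) for i in range(n_chroms)]
    chrom_lengths: dict[str, int] = {}
    features: list[FeatureAnchor] = []
    g = 0
    for ci, n_on_chrom in enumerate(per_chrom, start=1):
        chrom = f"chr{ci}"
        chrom_lengths[chrom] = 2 * margin + max(n_on_chrom - 1, 0) * gene_spacing + gene_spacing
        for j in range(n_on_chrom):
            g += 1
            features.append(
                FeatureAnchor(
                    id=f"gene{g:04d}",
                    chrom=chrom,
                    anchor_pos=margin + j * gene_spacing,
                    strand="+" if g % 2 else "-",
                )
            )
    return chrom_lengths, features


def build_model(
    chrom_lengths: Mapping[str, int],
    features: Sequence[FeatureAnchor],
    ndr_width: int = 150,
    plus_one_offset: int = 60,
    repeat_length: int = 154,
    n_nucleosomes_per_array: int = 10,
    occupancy: float = 0.9,
    fuzziness_sd: float = 10.0,
    background_rate: float = 2.0,
) -> ChromatinModel:
    """Plant phased nucleosome arrays at every feature anchor.

    For a + strand TSS the +1 center is ``anchor + plus_one_offset`` and
    center j (1-based) is ``anchor + plus_one_offset + (j-1)·repeat``; the
    −1 nucleosome mirrors the +1 across the NDR
    (``anchor − ndr_width − plus_one_offset``).  − strand features mirror
    everything.  Nucleosomes that would extend past a chromosome end are
    trimmed with a warning.
    """
    if not 0.0 <= occupancy <= 1.0:
        raise ValueError("occupancy must be in [0, 1]")
    if repeat_length <= 0 or fuzziness_sd < 0:
        raise ValueError("repeat_length must be > 0 and fuzziness_sd >= 0")
    nucleosomes: list[Nucleosome] = []
    n_trimmed = 0
    for feat in features:
        if feat.chrom not in chrom_lengths:
            raise ValueError(f"feature {feat.id!r}: unknown chromosome {feat.chrom!r}")
        length = chrom_lengths[feat.chrom]
        sign = 1 if feat.strand == "+" else -1
        centers = [(-1, feat.anchor_pos - sign * (ndr_width + plus_one_offset))]
        for j in range(n_nucleosomes_per_array):
            centers.append(
                (j + 1, feat.anchor_pos + sign * (plus_one_offset + j * repeat_length))
            )
        for index, center in centers:
            if center - 100 < 0 or center + 100 > length:
                n_trimmed += 1
                continue
            nucleosomes.append(
                Nucleosome(feature_id=feat.id, chrom=feat.chrom, center=int(center),
                           index_in_array=index)
            )
    if n_trimmed:
        logger.warning("trimmed %d nucleosome(s) extending past chromosome ends", n_trimmed)
    return ChromatinModel(
        chrom_lengths=dict(chrom_lengths),
        features=list(features),
        nucleosomes=nucleosomes,
        ndr_width=ndr_width,
        plus_one_offset=plus_one_offset,
        repeat_length=repeat_length,
        n_nucleosomes_per_array=n_nucleosomes_per_array,
        occupancy=occupancy,
        fuzziness_sd=fuzziness_sd,
        background_rate=background_rate,
    )


@dataclass
class SimulatedReads:
    """One simulated sequencing run: fragments plus per-nucleosome truth."""

    model: ChromatinModel
    condition: ConditionSpec
    digestion: DigestionSpec
    seed: int
    # parallel arrays over fragments, sorted by (chrom, start)
    chroms: list[str] = field(default_factory=list)
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    lengths: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    fragment_counts: dict[int, int] = field(default_factory=dict)  # nucleosome idx -> n

    @property
    def n_fragments(self) -> int:
        return len(self.chroms)

    def write_sam(self, sink: str | Path | IO[str]) -> None:
        """Emit fragments as proper SAM pairs (flags 99/147, symmetric ±TLEN)."""

        def _emit(fh: IO[str]) -> None:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n")
            for chrom, length in self.model.chrom_lengths.items():
                fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
            fh.write(
                f"@PG\tID:nucparticle\tPN:nucparticle-simulate"
                f"\tCL:condition={self.condition.label}"
                f" digestion={self.digestion.level} seed={self.seed}\n"
            )
            for i, (chrom, start, flen) in enumerate(
                zip(self.chroms, self.starts, self.lengths)
            ):
                name = f"frag{i:08d}"
                rlen = min(READ_LENGTH, int(flen))
                pos1 = int(start) + 1  # SAM is 1-based
                pos2 = int(start) + int(flen) - rlen + 1
                cigar = f"{rlen}M"
                fh.write(
                    f"{name}\t99\t{chrom}\t{pos1}\t42\t{cigar}\t=\t{pos2}\t{int(flen)}\t*\t*\n"
                )
                fh.write(
                    f"{name}\t147\t{chrom}\t{pos2}\t42\t{cigar}\t=\t{pos1}\t{-int(flen)}\t*\t*\n"
                )

        if isinstance(sink, (str, Path)):
            with open(sink, "wt", encoding="utf-8") as fh:
                _emit(fh)
        else:
            _emit(sink)

    def write_ground_truth(self, path: str | Path) -> None:
        """TSV of planted nucleosomes with realised fragment counts."""
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("chrom\tcenter\tfeature_id\tindex_in_array\tn_fragments\n")
            for i, nuc in enumerate(self.model.nucleosomes):
                fh.write(
                    f"{nuc.chrom}\t{nuc.center}\t{nuc.feature_id}\t{nuc.index_in_array}"
                    f"\t{self.fragment_counts.get(i, 0)}\n"
                )


def simulate_fragments(
    model: ChromatinModel,
    condition: ConditionSpec = WILDTYPE,
    digestion: DigestionSpec = LOW_DIGESTION,
    mean_frags_per_nucleosome: float = 50.0,
    seed: int = 0,
) -> SimulatedReads:
    """Draw one sequencing run from the chromatin model.

    Per nucleosome: ``Poisson(mean · occupancy · occupancy_scale)``
    fragments, centers jittered ``Normal(0, fuzziness_sd · fuzziness_scale)``,
    lengths ``round(Normal(fragment_mean, fragment_sd))`` clamped to
    [50, 400].  Background fragments arrive uniformly at
    ``background_rate`` per kb.  Deterministic given the seed (byte-identical
    SAM on re-run).
    """
    if mean_frags_per_nucleosome < 0:
        raise ValueError("mean_frags_per_nucleosome must be >= 0")
    rng = np.random.default_rng(seed)
    chrom_index = {c: k for k, c in enumerate(model.chrom_lengths)}
    chrom_names = list(model.chrom_lengths)
    lengths_arr = np.asarray([model.chrom_lengths[c] for c in chrom_names], dtype=np.int64)

    rate = mean_frags_per_nucleosome * model.occupancy * condition.occupancy_scale
    n_nucs = len(model.nucleosomes)
    counts = rng.poisson(rate, size=n_nucs) if n_nucs else np.empty(0, dtype=np.int64)
    total = int(counts.sum())

    nuc_chrom_idx = np.asarray(
        [chrom_index[n.chrom] for n in model.nucleosomes], dtype=np.int64
    )
    nuc_centers = np.asarray([n.center for n in model.nucleosomes], dtype=np.int64)
    frag_chrom_idx = np.repeat(nuc_chrom_idx, counts)
    frag_center = np.repeat(nuc_centers, counts).astype(float)
    sd = model.fuzziness_sd * condition.fuzziness_scale
    frag_center += rng.normal(0.0, sd, size=total) if sd > 0 else 0.0

    # background: uniform over each chromosome
    bg_counts = rng.poisson(model.background_rate * lengths_arr / 1000.0)
    bg_chrom_idx = np.repeat(np.arange(len(chrom_names)), bg_counts)
    bg_center = rng.uniform(0, lengths_arr[bg_chrom_idx]) if bg_chrom_idx.size else np.empty(0)

    all_chrom_idx = np.concatenate([frag_chrom_idx, bg_chrom_idx])
    all_center = np.concatenate([frag_center, bg_center])
    n_all = all_center.size
    flen = np.clip(
        np.rint(rng.normal(digestion.fragment_mean, digestion.fragment_sd, size=n_all)),
        FRAGMENT_MIN, FRAGMENT_MAX,
    ).astype(np.int64)
    starts = np.rint(all_center).astype(np.int64) - flen // 2
    clen = lengths_arr[all_chrom_idx]
    starts = np.clip(starts, 0, np.maximum(clen - flen, 0))

    order = np.lexsort((starts, all_chrom_idx))
    return SimulatedReads(
        model=model,
        condition=condition,
        digestion=digestion,
        seed=seed,
        chroms=[chrom_names[i] for i in all_chrom_idx[order]],
        starts=starts[order],
        lengths=flen[order],
        fragment_counts={i: int(c) for i, c in enumerate(counts)},
    )


def size_class_retention(digestion: DigestionSpec, size_class: SizeClassSpec) -> float:
    """Expected fraction of fragments whose length falls in the size class."""
    lo = (size_class.lower_bp - 0.5 - digestion.fragment_mean) / digestion.fragment_sd
    hi = (size_class.upper_bp + 0.5 - digestion.fragment_mean) / digestion.fragment_sd
    return float(norm.cdf(hi) - norm.cdf(lo))


def expected_summit_height(
    mean_frags_per_nucleosome: float,
    occupancy: float,
    fuzziness_sd: float,
    bin_width: int = 10,
    retention: float = 1.0,
) -> float:
    """Expected 3-bin-moving-average summit height over a planted nucleosome.

    The midpoints of a nucleosome's fragments fall Normal(center, sd); the
    3-bin window around the summit captures the mass within ±1.5 bins, and
    the moving average divides it by 3.
    """
    n = mean_frags_per_nucleosome * occupancy * retention
    half = 1.5 * bin_width
    if fuzziness_sd <= 0:
        mass = 1.0
    else:
        mass = float(norm.cdf(half / fuzziness_sd) - norm.cdf(-half / fuzziness_sd))
    return n * mass / 3.0


def suggested_peak_threshold(
    model: ChromatinModel,
    condition: ConditionSpec,
    digestion: DigestionSpec,
    mean_frags_per_nucleosome: float,
    size_class: SizeClassSpec,
) -> float:
    """Depth-scaled peak threshold: half the expected smoothed summit height.

    The genome-scale threshold of 25 plays the role of "well below a
    typical summit, well above background" at real sequencing depth; this
    reproduces that role analytically for an arbitrary simulated depth.
    """
    h = expected_summit_height(
        mean_frags_per_nucleosome,
        model.occupancy * condition.occupancy_scale,
        model.fuzziness_sd * condition.fuzziness_scale,
        retention=size_class_retention(digestion, size_class),
    )
    return 0.5 * h


@dataclass
class RecoveryReport:
    n_truth: int
    n_recovered: int
    recovery_fraction: float
    n_peaks: int
    n_false_positive: int
    false_positives_per_kb: float
    tolerance_bp: int


def evaluate_recovery(
    peaks: Sequence[PeakCall], model: ChromatinModel, tolerance_bp: int = 10
) -> RecoveryReport:
    """Score called summits against the planted centers.

    A planted center is recovered when some summit on its chromosome lies
    within ``tolerance_bp`` of it; a summit matching no center within the
    tolerance is a false positive, rated per kb of genome.
    """
    centers = model.centers_by_chrom()
    peaks_by_chrom: dict[str, list[int]] = {}
    for p in peaks:
        peaks_by_chrom.setdefault(p.chrom, []).append(p.summit_pos)

    n_truth = sum(len(c) for c in centers.values())
    n_recovered = 0
    n_false = 0
    n_peaks = 0
    for chrom, cents in centers.items():
        summits = np.asarray(sorted(peaks_by_chrom.get(chrom, [])), dtype=np.int64)
        n_peaks += summits.size
        if summits.size and cents.size:
            idx = np.searchsorted(summits, cents)
            near_lo = np.abs(summits[np.clip(idx - 1, 0, summits.size - 1)] - cents)
            near_hi = np.abs(summits[np.clip(idx, 0, summits.size - 1)] - cents)
            n_recovered += int(np.sum(np.minimum(near_lo, near_hi) <= tolerance_bp))
            jdx = np.searchsorted(cents, summits)
            s_lo = np.abs(cents[np.clip(jdx - 1, 0, cents.size - 1)] - summits)
            s_hi = np.abs(cents[np.clip(jdx, 0, cents.size - 1)] - summits)
            n_false += int(np.sum(np.minimum(s_lo, s_hi) > tolerance_bp))
        else:
            n_false += summits.size
    # stray peaks on chromosomes with no planted centers at all
    for chrom, summits in peaks_by_chrom.items():
        if chrom not in centers:
            n_false += len(summits)
            n_peaks += len(summits)
    genome_kb = sum(model.chrom_lengths.values()) / 1000.0
    return RecoveryReport(
        n_truth=n_truth,
        n_recovered=n_recovered,
        recovery_fraction=n_recovered / n_truth if n_truth else 0.0,
        n_peaks=n_peaks,
        n_false_positive=n_false,
        false_positives_per_kb=n_false / genome_kb if genome_kb else 0.0,
        tolerance_bp=tolerance_bp,
    )


def depleted_condition(occupancy_scale: float = 0.7, fuzziness_scale: float = 2.0) -> ConditionSpec:
    return ConditionSpec(
        label="depleted", occupancy_scale=occupancy_scale, fuzziness_scale=fuzziness_scale
    )
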