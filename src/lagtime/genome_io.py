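"""Genome geometry and coverage ingestion.

Defines the circular-chromosome layout (origins, terminus windows, special
loci, masked intervals) and turns sequencing output — indexed SAM/BAM,
per-base depth tables, bedGraph, or pre-binned TSV — into masked, binned
read-count profiles. All coordinates are 0-based, half-open: a bin
``[s, s + w)`` owns positions ``s .. s + w - 1``.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Chromosome",
    "SpecialLocus",
    "GenomeLayout",
    "BinnedCoverage",
    "bins_from_alignments",
    "bins_from_depth_table",
    "bins_from_tsv",
    "apply_masks",
]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    circular: bool = True


@dataclass(frozen=True)
class SpecialLocus:
    """A named locus such as crtS, oriC2 or an rDNA operon.

    ``orientation`` records the transcription direction relative to
    replication: ``codirectional``, ``head-on`` or None.
    """

    name: str
    chromosome: str
    position: int
    orientation: str | None = None


@dataclass
class GenomeLayout:
    """Circular chromosome geometry with replication landmarks.

    Parameters
    ----------
    chromosomes
        One :class:`Chromosome` per replicon.
    origins
        Map chromosome name -> origin position (bp). Exactly one per
        chromosome.
    terminus
        Map chromosome name -> ``(position, exclusion_half_width)``. Bins
        within the exclusion window are dropped from fits because fork
        motion is not unidirectional there.
    special_loci
        Named positions (crtS, oriC2, rDNA sites, ...).
    direction_map
        Optional ``(chromosome, start, end, label)`` intervals labelling
        regions replicated in the ``retrograde`` (reverse of wild-type)
        or ``antegrade`` direction, for ectopic-origin strains. Labels
        override the plain left/right arm label of loci they contain.
    masked_intervals
        ``(chromosome, start, end)`` intervals excluded from analysis.
    """

    chromosomes: list[Chromosome]
    origins: dict[str, int]
    terminus: dict[str, tuple[int, int]] = field(default_factory=dict)
    special_loci: list[SpecialLocus] = field(default_factory=list)
    direction_map: list[tuple[str, int, int, str]] = field(default_factory=list)
    masked_intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        by_name = {c.name: c for c in self.chromosomes}
        for name in names:
            if name not in self.origins:
                raise ValueError(f"chromosome {name!r} has no origin")
        for name, pos in self.origins.items():
            self._check_pos(by_name, name, pos, "origin")
        for name, (pos, half) in self.terminus.items():
            self._check_pos(by_name, name, pos, "terminus")
            if half < 0:
                raise ValueError("terminus exclusion half-width must be >= 0")
        for locus in self.special_loci:
            self._check_pos(by_name, locus.chromosome, locus.position, locus.name)
        for chrom, start, end, _ in self.direction_map:
            self._check_interval(by_name, chrom, start, end)
        for chrom, start, end in self.masked_intervals:
            self._check_interval(by_name, chrom, start, end)

    @staticmethod
    def _check_pos(by_name, chrom: str, pos: int, what: str) -> None:
        if chrom not in by_name:
            raise ValueError(f"{what}: unknown chromosome {chrom!r}")
        if not 0 <= pos < by_name[chrom].length:
            raise ValueError(
                f"{what}: position {pos} outside [0, {by_name[chrom].length}) on {chrom}"
            )

    @staticmethod
    def _check_interval(by_name, chrom: str, start: int, end: int) -> None:
        if chrom not in by_name:
            raise ValueError(f"interval on unknown chromosome {chrom!r}")
        if not (0 <= start < end <= by_name[chrom].length):
            raise ValueError(
                f"interval [{start}, {end}) not within chromosome {chrom!r}"
            )

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def locus(self, name: str) -> SpecialLocus:
        for loc in self.special_loci:
            if loc.name == name:
                return loc
        raise KeyError(name)

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "chromosomes": [
                {"name": c.name, "length": c.length, "circular": c.circular}
                for c in self.chromosomes
            ],
            "origins": dict(self.origins),
            "terminus": {k: list(v) for k, v in self.terminus.items()},
            "special_loci": [
                {
                    "name": s.name,
                    "chromosome": s.chromosome,
                    "position": s.position,
                    "orientation": s.orientation,
                }
                for s in self.special_loci
            ],
            "direction_map": [list(t) for t in self.direction_map],
            "masked_intervals": [list(t) for t in self.masked_intervals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeLayout":
        return cls(
            chromosomes=[Chromosome(**c) for c in d["chromosomes"]],
            origins=dict(d["origins"]),
            terminus={k: tuple(v) for k, v in d.get("terminus", {}).items()},
            special_loci=[SpecialLocus(**s) for s in d.get("special_loci", [])],
            direction_map=[tuple(t) for t in d.get("direction_map", [])],
            masked_intervals=[tuple(t) for t in d.get("masked_intervals", [])],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        return hashlib.md5(
            yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class ChromBins:
    """Bins tiling one chromosome; the final bin may be short."""

    starts: np.ndarray  # int64, 0-based bin start coordinates
    widths: np.ndarray  # int64
    counts: np.ndarray  # float64, >= 0 (integer-valued for read input)
    mask: np.ndarray  # bool, True = excluded from fits

    def __post_init__(self) -> None:
        n = len(self.starts)
        if not (len(self.widths) == len(self.counts) == len(self.mask) == n):
            raise ValueError("bin array length mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative bin counts")


@dataclass
class BinnedCoverage:
    """Per-bin read counts tiling each chromosome, with masking.

    Masked bins keep their counts (masking never alters counts, only
    flags) and are included in ``total_reads`` but excluded from fits.
    """

    bin_size: int
    chroms: dict[str, ChromBins]

    @property
    def total_reads(self) -> float:
        return float(sum(cb.counts.sum() for cb in self.chroms.values()))

    def midpoints(self, name: str) -> np.ndarray:
        cb = self.chroms[name]
        return cb.starts + cb.widths / 2.0

    def copy(self) -> "BinnedCoverage":
        return BinnedCoverage(
            self.bin_size,
            {
                k: ChromBins(
                    cb.starts.copy(), cb.widths.copy(), cb.counts.copy(), cb.mask.copy()
                )
                for k, cb in self.chroms.items()
            },
        )

    # ---- I/O -----------------------------------------------------------
    def to_tsv(self, path, layout: GenomeLayout | None = None, **meta) -> None:
        """Write the canonical binned-profile TSV.

        Header comments record the bin size, the layout hash and any
        masking parameters passed as keyword arguments.
        """
        rows = []
        for name, cb in self.chroms.items():
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "start": cb.starts,
                        "end": cb.starts + cb.widths,
                        "count": cb.counts,
                        "mask": cb.mask.astype(int),
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        with open(path, "w") as fh:
            fh.write(f"# bin_size={self.bin_size}\n")
            if layout is not None:
                fh.write(f"# layout_hash={layout.content_hash()}\n")
            for k, v in meta.items():
                fh.write(f"# {k}={v}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinnedCoverage":
        bin_size = None
        with open(path) as fh:
            header_lines = []
            for line in fh:
                if line.startswith("#"):
                    header_lines.append(line)
                else:
                    break
        for line in header_lines:
            if "bin_size=" in line:
                bin_size = int(line.split("bin_size=")[1].strip())
        df = pd.read_csv(path, sep="\t", comment="#")
        chroms = {}
        for name, g in df.groupby("chrom", sort=False):
            starts = g["start"].to_numpy(dtype=np.int64)
            widths = (g["end"] - g["start"]).to_numpy(dtype=np.int64)
            chroms[str(name)] = ChromBins(
                starts,
                widths,
                g["count"].to_numpy(dtype=float),
                g["mask"].to_numpy(dtype=bool),
            )
        if bin_size is None:
            bin_size = int(max(cb.widths.max() for cb in chroms.values()))
        return cls(bin_size, chroms)

    def to_bedgraph(self, path) -> None:
        """Write per-bin mean depth (count / bin width) as bedGraph."""
        with open(path, "w") as fh:
            for name, cb in self.chroms.items():
                for s, w, c in zip(cb.starts, cb.widths, cb.counts):
                    fh.write(f"{name}\t{s}\t{s + w}\t{c / w}\n")


def _empty_bins(layout: GenomeLayout, bin_size: int) -> dict[str, ChromBins]:
    chroms = {}
    for c in layout.chromosomes:
        starts = np.arange(0, c.length, bin_size, dtype=np.int64)
        widths = np.minimum(bin_size, c.length - starts)
        chroms[c.name] = ChromBins(
            starts,
            widths,
            np.zeros(len(starts)),
            np.zeros(len(starts), dtype=bool),
        )
    return chroms


def bins_from_alignments(
    alignment_path,
    layout: GenomeLayout,
    bin_size: int = 1000,
    min_mapq: int = 20,
) -> BinnedCoverage:
    """Bin primary alignments by leftmost mapped coordinate.

    Each primary, non-duplicate, non-supplementary alignment with mapping
    quality >= ``min_mapq`` contributes one count to the bin containing
    its leftmost mapped coordinate. Zero-count bins are flagged masked
    (unmappable repetitive sequence leaves gaps in real data).

    The input must be coordinate-sorted; BAM/CRAM must be indexed, and a
    plain SAM must declare ``SO:coordinate`` in its header.
    """
    import pysam

    if bin_size < 100:
        raise ValueError("bin_size must be >= 100 bp")
    af = pysam.AlignmentFile(str(alignment_path))
    try:
        for ref in af.references:
            if ref not in layout.names:
                raise ValueError(
                    f"reference {ref!r} in {alignment_path} is not in the genome layout"
                )
        is_sam = af.format == "SAM"
        if is_sam:
            so = (af.header.get("HD") or {}).get("SO")
            if so != "coordinate":
                raise ValueError(
                    f"{alignment_path}: SAM input must be coordinate-sorted "
                    f"(header SO={so!r})"
                )
        elif not af.has_index():
            raise ValueError(
                f"{alignment_path}: BAM/CRAM input must be coordinate-sorted and indexed"
            )
        chroms = _empty_bins(layout, bin_size)
        iterator = af.fetch(until_eof=True) if is_sam else af.fetch()
        for aln in iterator:
            if (
                aln.is_unmapped
                or aln.is_secondary
                or aln.is_supplementary
                or aln.is_duplicate
                or aln.mapping_quality < min_mapq
            ):
                continue
            cb = chroms[aln.reference_name]
            cb.counts[aln.reference_start // bin_size] += 1
    finally:
        af.close()
    for cb in chroms.values():
        cb.mask |= cb.counts == 0
    return BinnedCoverage(bin_size, chroms)


def bins_from_depth_table(
    depth_path,
    layout: GenomeLayout,
    bin_size: int = 1000,
    dialect: str = "depth",
) -> BinnedCoverage:
    """Bin a per-base depth TSV or a bedGraph into depth mass per bin.

    ``dialect='depth'``: columns (chrom, pos, depth) with 1-based
    positions; each base contributes its depth to its bin.
    ``dialect='bedgraph'``: columns (chrom, start, end, value), 0-based
    half-open; an interval contributes ``value *`` (bases of overlap) to
    each bin it overlaps.

    The dialect is declared by the caller, never guessed.
    """
    if dialect not in ("depth", "bedgraph"):
        raise ValueError(f"unknown dialect {dialect!r}")
    chroms = _empty_bins(layout, bin_size)
    lengths = {c.name: c.length for c in layout.chromosomes}
    if dialect == "depth":
        df = pd.read_csv(
            depth_path, sep="\t", comment="#", header=None,
            names=["chrom", "pos", "depth"],
        )
        for name, g in df.groupby("chrom", sort=False):
            name = str(name)
            if name not in chroms:
                raise ValueError(f"unknown chromosome {name!r} in depth table")
            pos0 = g["pos"].to_numpy(dtype=np.int64) - 1  # 1-based -> 0-based
            if pos0.min() < 0 or pos0.max() >= lengths[name]:
                raise ValueError(f"depth position beyond chromosome {name!r} length")
            np.add.at(
                chroms[name].counts, pos0 // bin_size, g["depth"].to_numpy(dtype=float)
            )
    else:
        df = pd.read_csv(
            depth_path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
        )
        for row in df.itertuples(index=False):
            name = str(row.chrom)
            if name not in chroms:
                raise ValueError(f"unknown chromosome {name!r} in bedGraph")
            if row.start < 0 or row.end > lengths[name] or row.start >= row.end:
                raise ValueError(
                    f"bedGraph interval [{row.start}, {row.end}) invalid on {name!r}"
                )
            cb = chroms[name]
            first = row.start // bin_size
            last = (row.end - 1) // bin_size
            for b in range(first, last + 1):
                lo = max(row.start, cb.starts[b])
                hi = min(row.end, cb.starts[b] + cb.widths[b])
                cb.counts[b] += row.value * (hi - lo)
    for cb in chroms.values():
        cb.mask |= cb.counts == 0
    return BinnedCoverage(bin_size, chroms)


bins_from_tsv = BinnedCoverage.from_tsv


def _running_median(values: np.ndarray, window: int, circular: bool) -> np.ndarray:
    n = len(values)
    if window > n:
        warnings.warn("median window larger than chromosome; reducing window")
        window = n if n % 2 == 1 else n - 1
    half = window // 2
    if circular:
        padded = np.concatenate([values[-half:], values, values[:half]])
    else:
        padded = np.concatenate(
            [np.repeat(values[0], half), values, np.repeat(values[-1], half)]
        )
    out = np.empty(n)
    # sliding_window_view keeps this O(n window log window) which is fine
    win = np.lib.stride_tricks.sliding_window_view(padded, window)
    out[:] = np.median(win, axis=1)
    return out


def apply_masks(
    cov: BinnedCoverage,
    layout: GenomeLayout,
    outlier_mad_k: float = 5.0,
    window: int = 21,
) -> BinnedCoverage:
    """Mask layout intervals and robust outliers.

    Bins overlapping ``layout.masked_intervals`` are masked. In addition,
    bins whose ln-count deviates from a running median (over unmasked
    neighbours) by more than ``outlier_mad_k`` robust standard deviations
    (1.4826 x MAD) are masked. The outlier pass iterates to a fixpoint so
    that the operation is idempotent. Counts are never altered.
    """
    if outlier_mad_k <= 0:
        raise ValueError("outlier_mad_k must be > 0")
    out = cov.copy()
    for chrom, start, end in layout.masked_intervals:
        cb = out.chroms[chrom]
        hit = (cb.starts < end) & (cb.starts + cb.widths > start)
        cb.mask |= hit
    for name, cb in out.chroms.items():
        circular = layout.chromosome(name).circular
        cb.mask |= cb.counts == 0
        for _ in range(20):  # fixpoint iteration
            keep = ~cb.mask
            vals = np.log(cb.counts[keep])
            if keep.sum() < 5:
                break
            med = _running_median(vals, window, circular)
            resid = vals - med
            sigma = 1.4826 * np.median(np.abs(resid))
            if sigma == 0:
                break
            new_outliers = np.abs(resid) > outlier_mad_k * sigma
            if not new_outliers.any():
                break
            idx = np.flatnonzero(keep)[new_outliers]
            cb.mask[idx] = True
    return out
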