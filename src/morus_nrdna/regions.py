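"""Coordinate system of the Morus nrDNA repeat unit.

The nrDNA cistron analysed here is a single 5814 bp sequence made of five
contiguous subregions in fixed order: 18S (1808 bp), ITS1 (215 bp), 5.8S
(163 bp), ITS2 (233 bp) and 26S (3395 bp).  ITS1-5.8S-ITS2 together form the
611 bp ITS span used for barcoding and for the CAPS assay.

All coordinates in this package are 1-based inclusive, matching the variant
positions the pipeline reports (e.g. the 13/16 bp insertion anchored at
position 1862 lies in ITS1).  BED export converts to the 0-based half-open
convention of that format.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

REGION_NAMES = ("18S", "ITS1", "5.8S", "ITS2", "26S")
DEFAULT_REGION_LENGTHS = (1808, 215, 163, 233, 3395)
ITS_REGIONS = frozenset({"ITS1", "5.8S", "ITS2"})


class CoordinateError(ValueError):
    """A position falls outside the region map."""


@dataclass(frozen=True)
class Region:
    """One nrDNA subregion with 1-based inclusive bounds."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"region {self.name}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"region {self.name}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class RegionMap:
    """Ordered, contiguous partition of the nrDNA unit into subregions."""

    regions: tuple[Region, ...]
    _starts: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("region map needs at least one region")
        if self.regions[0].start != 1:
            raise ValueError("first region must start at 1")
        for prev, cur in zip(self.regions, self.regions[1:]):
            if cur.start != prev.end + 1:
                raise ValueError(
                    f"regions {prev.name} and {cur.name} are not contiguous"
                )
        object.__setattr__(
            self, "_starts", tuple(r.start for r in self.regions)
        )

    @property
    def total_length(self) -> int:
        return self.regions[-1].end

    def assign(self, pos: int) -> str:
        """Name of the unique region containing 1-based position ``pos``."""
        if not 1 <= pos <= self.total_length:
            raise CoordinateError(
                f"position {pos} outside nrDNA [1, {self.total_length}]"
            )
        i = bisect.bisect_right(self._starts, pos) - 1
        return self.regions[i].name

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def its_span(self) -> tuple[int, int]:
        """1-based inclusive bounds of the ITS (ITS1 start .. ITS2 end)."""
        return self.region("ITS1").start, self.region("ITS2").end

    def pooled_region(self, pos: int) -> str:
        """Region name with ITS1/5.8S/ITS2 pooled into a single 'ITS' bin."""
        name = self.assign(pos)
        return "ITS" if name in ITS_REGIONS else name


def default_region_map() -> RegionMap:
    """The packaged 5814 bp map: 18S, ITS1, 5.8S, ITS2, 26S."""
    regions = []
    start = 1
    for name, length in zip(REGION_NAMES, DEFAULT_REGION_LENGTHS):
        regions.append(Region(name, start, start + length - 1))
        start += length
    return RegionMap(tuple(regions))


def write_bed(region_map: RegionMap, path: str | Path, chrom: str = "nrDNA") -> None:
    """Write the map as BED (0-based half-open) columns chrom/start/end/name."""
    with open(path, "w") as fh:
        for r in region_map.regions:
            fh.write(f"{chrom}\t{r.start - 1}\t{r.end}\t{r.name}\n")


def read_bed(path: str | Path) -> RegionMap:
    """Read a region map written by :func:`write_bed`."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"BED line needs 4 columns: {line!r}")
            _, start0, end, name = fields[:4]
            regions.append(Region(name, int(start0) + 1, int(end)))
    regions.sort(key=lambda r: r.start)
    return RegionMap(tuple(regions))


def read_reference(path: str | Path, region_map: RegionMap | None = None) -> str:
    """Read a single-record reference FASTA; optionally validate its length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected one reference record, found {len(records)}")
    seq = str(records[0].seq).upper()
    if region_map is not None and len(seq) != region_map.total_length:
        raise ValueError(
            f"reference length {len(seq)} does not match region map "
            f"total {region_map.total_length}"
        )
    return seq


def assign_region(pos: int, region_map: RegionMap) -> str:
    """Functional alias for :meth:`RegionMap.assign`."""
    return region_map.assign(pos)
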