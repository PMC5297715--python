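"""Exome homozygosity mapping (runs of homozygosity from read counts).

The map is built from autosomal exome sites with at least 20x coverage.
Each marker is called from its variant allele fraction f = variant
reads / depth:

* homozygous  — f >= 0.95 and depth >= 5,
* heterozygous — 0.30 <= f <= 0.70 and depth >= 10,
* ambiguous   — everything else (f < 0.30, 0.70 < f < 0.95, or a failed
  depth floor). Ambiguous markers stay in the map and count toward the
  window size and gap chain but never toward the heterozygote budget.

A window of 500 consecutive markers qualifies when it contains at most
2 heterozygous markers and no adjacent-marker gap above 500 kb. Windows
slide one marker at a time and never straddle a chromosome boundary.
Overlapping or marker-adjacent qualified windows coalesce into maximal
runs; each run, trimmed to its outermost homozygous-called markers,
is emitted as a homozygous region when it spans at least 1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import AUTOSOMES, chromosome_sort_key

__all__ = [
    "RohParameters",
    "Marker",
    "Window",
    "HomozygousRegion",
    "MarkerMap",
    "classify_marker",
    "build_marker_map",
    "scan_windows",
    "oracle_scan",
    "coalesce_windows",
    "map_homozygosity",
]

HOM, HET, AMBIGUOUS = 0, 1, 2
_CALL_NAMES = {HOM: "homozygous", HET: "heterozygous", AMBIGUOUS: "ambiguous"}


@dataclass(frozen=True)
class RohParameters:
    """Thresholds of the homozygosity-mapping pipeline (defaults are the
    study's: 20x map inclusion; hom call at VAF >= 0.95 and 5x; het call
    at VAF 0.30–0.70 and 10x; 500-marker windows with <= 2 hets and
    <= 500 kb gaps; regions >= 1 Mb)."""

    min_map_depth: int = 20
    hom_min_fraction: float = 0.95
    hom_min_depth: int = 5
    het_lo: float = 0.30
    het_hi: float = 0.70
    het_min_depth: int = 10
    window_markers: int = 500
    max_het_per_window: int = 2
    max_gap_bp: int = 500_000
    min_region_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0 < self.het_lo < self.het_hi < self.hom_min_fraction <= 1:
            raise ValueError("require 0 < het_lo < het_hi < hom_min_fraction <= 1")
        if self.window_markers < 1:
            raise ValueError("window_markers must be >= 1")


@dataclass(frozen=True)
class Marker:
    chromosome: str
    position: int
    depth: int
    variant_reads: int

    def __post_init__(self) -> None:
        if self.variant_reads > self.depth:
            raise ValueError("variant_reads exceeds depth")


@dataclass(frozen=True)
class Window:
    chromosome: str
    first_marker_index: int
    last_marker_index: int
    qualified: bool
    het_count: int
    max_internal_gap_bp: int


@dataclass(frozen=True)
class HomozygousRegion:
    chromosome: str
    start_bp: int
    end_bp: int
    n_markers: int
    n_het_markers: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


#: per-chromosome ordered marker arrays
MarkerMap = dict  # chrom -> {"positions": ndarray, "calls": ndarray, "depths": ndarray}


def classify_marker(depth: int, variant_reads: int, params: RohParameters = RohParameters()) -> str:
    """Call one marker from depth and variant-supporting reads."""
    if depth == 0:
        raise ValueError("uncovered site: depth is zero")
    if variant_reads > depth:
        raise ValueError("variant_reads exceeds depth")
    f = variant_reads / depth
    if f >= params.hom_min_fraction and depth >= params.hom_min_depth:
        return "homozygous"
    if params.het_lo <= f <= params.het_hi and depth >= params.het_min_depth:
        return "heterozygous"
    return "ambiguous"


def _classify_codes(depths: np.ndarray, reads: np.ndarray, params: RohParameters) -> np.ndarray:
    f = reads / depths
    calls = np.full(len(depths), AMBIGUOUS, dtype=np.int8)
    calls[(f >= params.hom_min_fraction) & (depths >= params.hom_min_depth)] = HOM
    het = (f >= params.het_lo) & (f <= params.het_hi) & (depths >= params.het_min_depth)
    calls[het & (calls != HOM)] = HET
    return calls


def build_marker_map(
    sites: Iterable[Marker] | pd.DataFrame,
    params: RohParameters = RohParameters(),
) -> MarkerMap:
    """Build per-chromosome ordered, classified marker lists.

    Keeps autosomal sites with depth >= ``min_map_depth``; sorts by
    position; collapses duplicate positions to the deepest record.
    """
    if isinstance(sites, pd.DataFrame):
        df = sites.rename(columns={"chrom": "chromosome", "pos": "position"}).copy()
    else:
        df = pd.DataFrame(
            [(m.chromosome, m.position, m.depth, m.variant_reads) for m in sites],
            columns=["chromosome", "position", "depth", "variant_reads"],
        )
    if df.empty:
        return {}
    df = df[df["chromosome"].isin(AUTOSOMES) & (df["depth"] >= params.min_map_depth)]
    out: MarkerMap = {}
    for chrom, sub in df.groupby("chromosome", sort=False):
        sub = sub.sort_values(["position", "depth"]).drop_duplicates("position", keep="last")
        positions = sub["position"].to_numpy(dtype=np.int64)
        depths = sub["depth"].to_numpy(dtype=np.int64)
        reads = sub["variant_reads"].to_numpy(dtype=np.int64)
        if np.any(depths == 0):
            raise ValueError("uncovered site: depth is zero")
        out[chrom] = {
            "positions": positions,
            "depths": depths,
            "variant_reads": reads,
            "calls": _classify_codes(depths, reads, params),
        }
    return dict(sorted(out.items(), key=lambda kv: chromosome_sort_key(kv[0])))


def scan_windows(marker_map: MarkerMap, params: RohParameters = RohParameters()) -> list[Window]:
    """Slide a ``window_markers``-wide window one marker at a time over
    each chromosome and qualify it on the het budget and gap ceiling."""
    w = params.window_markers
    windows: list[Window] = []
    for chrom, data in marker_map.items():
        positions, calls = data["positions"], data["calls"]
        n = len(positions)
        if n < w:
            continue
        is_het = (calls == HET).astype(np.int64)
        het_counts = np.convolve(is_het, np.ones(w, dtype=np.int64), mode="valid")
        gaps = np.diff(positions)
        if w > 1:
            gap_view = np.lib.stride_tricks.sliding_window_view(gaps, w - 1)
            max_gaps = gap_view.max(axis=1)
        else:
            max_gaps = np.zeros(n, dtype=np.int64)
        qualified = (het_counts <= params.max_het_per_window) & (max_gaps <= params.max_gap_bp)
        for i in range(n - w + 1):
            windows.append(
                Window(
                    chromosome=chrom,
                    first_marker_index=i,
                    last_marker_index=i + w - 1,
                    qualified=bool(qualified[i]),
                    het_count=int(het_counts[i]),
                    max_internal_gap_bp=int(max_gaps[i]),
                )
            )
    return windows


def oracle_scan(marker_map: MarkerMap, params: RohParameters = RohParameters()) -> list[Window]:
    """Reference window scan: enumerates every window explicitly and
    re-checks both constraints by full iteration (no incremental
    bookkeeping). Intended for small maps."""
    w = params.window_markers
    windows: list[Window] = []
    for chrom, data in marker_map.items():
        positions = [int(p) for p in data["positions"]]
        calls = [int(c) for c in data["calls"]]
        n = len(positions)
        for i in range(n - w + 1):
            het = 0
            max_gap = 0
            for j in range(i, i + w):
                if calls[j] == HET:
                    het += 1
                if j > i:
                    gap = positions[j] - positions[j - 1]
                    if gap > max_gap:
                        max_gap = gap
            ok = het <= params.max_het_per_window and max_gap <= params.max_gap_bp
            windows.append(Window(chrom, i, i + w - 1, ok, het, max_gap))
    return windows


def coalesce_windows(
    windows: Sequence[Window],
    marker_map: MarkerMap,
    params: RohParameters = RohParameters(),
) -> list[HomozygousRegion]:
    """Merge overlapping or marker-adjacent qualified windows into maximal
    runs and emit runs of at least ``min_region_bp``.

    Each run is trimmed to its outermost homozygous-called markers before
    measuring its span, so region boundaries are confident homozygous
    sites rather than the stray heterozygous or ambiguous markers a
    window's het budget tolerates at the edge of a true run.
    """
    regions: list[HomozygousRegion] = []
    by_chrom: dict[str, list[Window]] = {}
    for win in windows:
        if win.qualified:
            by_chrom.setdefault(win.chromosome, []).append(win)
    for chrom, wins in by_chrom.items():
        data = marker_map[chrom]
        positions, calls = data["positions"], data["calls"]
        wins.sort(key=lambda w: w.first_marker_index)
        runs: list[list[int]] = []
        for win in wins:
            if runs and win.first_marker_index <= runs[-1][1] + 1:
                runs[-1][1] = max(runs[-1][1], win.last_marker_index)
            else:
                runs.append([win.first_marker_index, win.last_marker_index])
        for first, last in runs:
            while first <= last and calls[first] != HOM:
                first += 1
            while last >= first and calls[last] != HOM:
                last -= 1
            if first > last:
                continue
            region = HomozygousRegion(
                chromosome=chrom,
                start_bp=int(positions[first]),
                end_bp=int(positions[last]),
                n_markers=int(last - first + 1),
                n_het_markers=int(np.sum(calls[first : last + 1] == HET)),
            )
            if region.length_bp >= params.min_region_bp:
                regions.append(region)
    regions.sort(key=lambda r: (chromosome_sort_key(r.chromosome), r.start_bp))
    return regions


def map_homozygosity(
    sites: Iterable[Marker] | pd.DataFrame,
    params: RohParameters = RohParameters(),
) -> list[HomozygousRegion]:
    """End-to-end homozygosity mapping: build the map, scan windows,
    coalesce into regions."""
    marker_map = build_marker_map(sites, params)
    windows = scan_windows(marker_map, params)
    return coalesce_windows(windows, marker_map, params)
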