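"""Runs-of-homozygosity detection from genotype calls.

A deterministic streak/window scan rather than a likelihood (LOD) model: a
run of homozygous calls extends through occasional heterozygous calls as long
as no trailing window of ``window_sites`` sites accumulates more than
``het_tolerance`` hets; runs separated by short physical gaps are merged, and
only segments exceeding the minimum span (strictly greater, matching the
">2 Mb" prioritization rule) with enough supporting sites are reported.
Computed on the full genotyped site set — rare-only sites are far too sparse
to define megabase-scale runs.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import Pedigree, VariantRecord, chrom_sort_key
from .inheritance import InheritanceCandidate


@dataclass(frozen=True)
class ROHSegment:
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    n_sites: int
    n_het: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("segment end before start")

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class ROHParams:
    min_length_bp: int = 2_000_000
    min_sites: int = 25
    het_tolerance: int = 1
    window_sites: int = 50
    max_gap_bp: int = 500_000

    def __post_init__(self) -> None:
        for name in ("min_sites", "window_sites"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # 0 disables the span threshold (comparison is strictly-greater)
        if self.min_length_bp < 0:
            raise ValueError("min_length_bp must be >= 0")
        if self.het_tolerance < 0 or self.max_gap_bp < 0:
            raise ValueError("het_tolerance and max_gap_bp must be >= 0")
        if self.het_tolerance >= self.window_sites:
            raise ValueError("het_tolerance must be < window_sites")


class UnsortedSitesError(ValueError):
    """Input sites are not sorted by (chrom, pos)."""


def _raw_runs(
    sites: Sequence[tuple[int, bool]], params: ROHParams
) -> list[tuple[int, int, int, int]]:
    """Scan one chromosome's (pos, is_het) sites into raw runs.

    Returns (start, end, n_sites, n_het) tuples.  A run is opened at a hom
    site, extended through hets while every trailing ``window_sites`` window
    holds at most ``het_tolerance`` hets, and closed (trimmed back to its last
    hom site) at the het that would break that bound.
    """
    runs = []
    cur: list[tuple[int, bool]] = []  # sites in the current run

    def close() -> None:
        nonlocal cur
        while cur and cur[-1][1]:  # trim trailing hets
            cur.pop()
        if cur:
            runs.append(
                (cur[0][0], cur[-1][0], len(cur), sum(1 for _, h in cur if h))
            )
        cur = []

    for pos, is_het in sites:
        if is_het:
            if not cur:
                continue  # runs open at hom sites only
            window = cur[-(params.window_sites - 1):] + [(pos, True)]
            if sum(1 for _, h in window if h) > params.het_tolerance:
                close()
                continue
        cur.append((pos, is_het))
    close()
    return runs


def detect_roh(
    sites: Sequence[tuple[str, int, str]], params: ROHParams | None = None
) -> list[ROHSegment]:
    """Detect ROH segments from (chrom, pos, zygosity) triples sorted by
    (chrom, pos).

    Zygosity strings follow :class:`GenotypeCall`: ``hom_ref``/``hom_alt``
    count as homozygous, ``het`` as heterozygous; ``missing`` calls are
    ignored (neither support nor interrupt a run).
    """
    params = params or ROHParams()
    by_chrom: dict[str, list[tuple[int, bool]]] = {}
    last_key: tuple[tuple[int, str], int] | None = None
    for chrom, pos, zyg in sites:
        key = (chrom_sort_key(chrom), pos)
        if last_key is not None and key < last_key:
            raise UnsortedSitesError(f"sites not sorted at {chrom}:{pos}")
        last_key = key
        if zyg == "missing":
            continue
        by_chrom.setdefault(chrom, []).append((pos, zyg == "het"))

    segments: list[ROHSegment] = []
    for chrom in sorted(by_chrom, key=chrom_sort_key):
        chrom_sites = by_chrom[chrom]
        positions = [p for p, _ in chrom_sites]
        runs = _raw_runs(chrom_sites, params)
        merged: list[list[int]] = []
        for start, end, n_sites, n_het in runs:
            if merged and start - merged[-1][1] - 1 < params.max_gap_bp:
                # sites between the two runs are the het interruptions that
                # broke the scan; merging must keep the joined run's overall
                # het rate within the window tolerance, otherwise chains of
                # merges would bridge arbitrarily het-dense stretches
                prev = merged[-1]
                lo = bisect.bisect_right(positions, prev[1])
                hi = bisect.bisect_left(positions, start)
                n_between = hi - lo
                hets = prev[3] + n_het + n_between
                sites_total = prev[2] + n_sites + n_between
                if hets * params.window_sites <= params.het_tolerance * sites_total:
                    prev[1] = end
                    prev[2] = sites_total
                    prev[3] = hets
                    continue
            merged.append([start, end, n_sites, n_het])
        for start, end, n_sites, n_het in merged:
            span = end - start + 1
            if span > params.min_length_bp and n_sites >= params.min_sites:
                segments.append(ROHSegment(chrom, start, end, n_sites, n_het))
    return segments


def proband_sites(
    records: Sequence[VariantRecord], pedigree: Pedigree
) -> list[tuple[str, int, str]]:
    """Extract the proband's sorted (chrom, pos, zygosity) site list."""
    proband = pedigree.proband.sample_id
    return [(v.chrom, v.pos, v.genotype(proband).zygosity) for v in records]


def annotate_in_roh(
    candidates: Iterable[InheritanceCandidate], segments: Sequence[ROHSegment]
) -> list[InheritanceCandidate]:
    """Set ``in_roh`` on homozygous candidates inside a segment.

    Compound-het candidates are heterozygous by definition and always False.
    """
    out = []
    for cand in candidates:
        if cand.model == "hom_recessive":
            v = cand.variants[0]
            cand.in_roh = any(seg.contains(v.chrom, v.pos) for seg in segments)
        else:
            cand.in_roh = False
        out.append(cand)
    return out
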