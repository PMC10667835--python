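"""Relating RNase E ends to exoribonuclease trimming sites.

After RNase E shears a transcript, the exposed 3' end is attacked by the
3'->5' exoribonucleases (PNPase, RNase II, RNase R), which run until a
stable stem-loop halts them.  The observable consequences are distance
relationships between site classes, all evaluated in transcript orientation
(5'->3' along the strand, never genomic left/right):

* a 3' RNase E end within +/-5 nt of a trimming stop (``stop_match``) or,
  failing that, of a trimming start (``start_match``); stop matches take
  priority when both are in tolerance;
* stop/start pairs of one enzyme, the start downstream of the stop within
  the enzyme's reach (300 nt for PNPase and RNase R, 10 nt for the weakly
  processive RNase II);
* a trimming start strictly upstream (< 10 nt) of a 5' RNase E end -- the
  signature of PNPase chewing up to the next RNase-E-generated 5' end;
* processing fragments: (rne5, rne3) pairs < 300 nt apart, and
  (start5, start3) pairs of one enzyme 50-300 nt apart, the footprint of a
  fragment cut out by the endonuclease and fully degraded by the exonuclease.

All pairings are deterministic: nearest-neighbor with greedy resolution,
ties toward the 5'-most position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

ENZYME_MAX_DISTANCE = {"pnp": 300, "rnr": 300, "rnb": 10}


@dataclass(frozen=True)
class Site:
    """Minimal strand-aware site used by the matching operations."""

    contig: str
    strand: str
    pos: int


@dataclass(frozen=True)
class RneExoLink:
    rne_site: Site
    exo_site: Site
    relation: str          # stop_match | start_match | rne5_upstream_start
    distance: int          # signed, transcript orientation (downstream > 0)


@dataclass(frozen=True)
class StopStartPair:
    enzyme: str
    stop: Site
    start: Site
    distance: int          # start - stop along the transcript, > 0


@dataclass(frozen=True)
class ProcessingFragment:
    contig: str
    strand: str
    five_prime: int
    three_prime: int
    length: int
    origin: str            # rne_pair | exo_full_degradation
    enzyme: str | None = None


def _tx_distance(a: Site, b: Site) -> int:
    """Signed distance from a to b in transcript orientation (>0: b downstream)."""
    d = b.pos - a.pos
    return d if a.strand == "+" else -d


def _same_track(a: Site, b: Site) -> bool:
    return a.contig == b.contig and a.strand == b.strand


def link_rne3(rne3_sites: list[Site],
              exo_stops: list[Site],
              exo_starts: list[Site],
              tolerance: int = 5) -> tuple[list[RneExoLink], dict[str, float]]:
    """Classify each 3' RNase E end against exo trimming stops and starts.

    A stop of any enzyme within +/-``tolerance`` nt wins (nearest, ties to
    the upstream site); otherwise the nearest start in tolerance; otherwise
    unmatched.  Returns the links plus the fraction of rne3 ends in each of
    the three categories (they sum to 1 when any rne3 ends exist).
    """
    links: list[RneExoLink] = []
    tally = Counter()
    for rne in rne3_sites:
        match = _nearest_in_tolerance(rne, exo_stops, tolerance)
        relation = "stop_match"
        if match is None:
            match = _nearest_in_tolerance(rne, exo_starts, tolerance)
            relation = "start_match"
        if match is None:
            tally["unmatched"] += 1
            continue
        tally[relation] += 1
        links.append(RneExoLink(rne, match, relation, _tx_distance(rne, match)))
    n = len(rne3_sites)
    fractions = {k: (tally[k] / n if n else 0.0)
                 for k in ("stop_match", "start_match", "unmatched")}
    return links, fractions


def _nearest_in_tolerance(ref: Site, sites: list[Site],
                          tolerance: int) -> Site | None:
    best: Site | None = None
    best_key: tuple[int, int] | None = None
    for s in sites:
        if not _same_track(ref, s):
            continue
        d = _tx_distance(ref, s)
        if abs(d) > tolerance:
            continue
        key = (abs(d), d)      # nearest; ties -> upstream (negative d)
        if best_key is None or key < best_key:
            best, best_key = s, key
    return best


def pair_stop_start(stops: list[Site], starts: list[Site],
                    enzyme: str) -> list[StopStartPair]:
    """Pair each trimming stop with the nearest downstream start of the same
    enzyme within the enzyme's maximum trimming distance.

    A start pairs with at most one stop; conflicts resolve nearest-wins
    (processed in ascending distance, ties to the 5'-most stop).
    """
    if enzyme not in ENZYME_MAX_DISTANCE:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    limit = ENZYME_MAX_DISTANCE[enzyme]
    candidates: list[tuple[int, int, int, Site, Site]] = []
    for i, stop in enumerate(stops):
        for j, start in enumerate(starts):
            if not _same_track(stop, start):
                continue
            d = _tx_distance(stop, start)
            if 0 < d <= limit:
                tie = stop.pos if stop.strand == "+" else -stop.pos
                candidates.append((d, tie, j, stop, start))
    used_stops: set[tuple[str, str, int]] = set()
    used_starts: set[int] = set()
    pairs: list[StopStartPair] = []
    for d, _tie, j, stop, start in sorted(candidates, key=lambda c: (c[0], c[1], c[2])):
        skey = (stop.contig, stop.strand, stop.pos)
        if skey in used_stops or j in used_starts:
            continue
        used_stops.add(skey)
        used_starts.add(j)
        pairs.append(StopStartPair(enzyme, stop, start, d))
    return sorted(pairs, key=lambda p: (p.stop.contig, p.stop.strand, p.stop.pos))


def link_rne5_to_start(rne5_sites: list[Site],
                       exo_starts: list[Site],
                       max_dist: int = 10) -> list[RneExoLink]:
    """Trimming starts strictly upstream of a 5' RNase E end by < max_dist nt."""
    links = []
    for rne in rne5_sites:
        for s in exo_starts:
            if not _same_track(rne, s):
                continue
            d = -_tx_distance(rne, s)   # >0 when the start is upstream
            if 0 < d < max_dist:
                links.append(RneExoLink(rne, s, "rne5_upstream_start", d))
    return links


def enumerate_fragments(rne5_sites: list[Site],
                        rne3_sites: list[Site],
                        start5_by_enzyme: dict[str, list[Site]],
                        start3_by_enzyme: dict[str, list[Site]],
                        rne_max: int = 300,
                        degrade_range: tuple[int, int] = (50, 300),
                        ) -> list[ProcessingFragment]:
    """Enumerate processing fragments.

    ``rne_pair``: every (rne5, rne3) with the 3' end 0 < d < ``rne_max`` nt
    downstream of the 5' end.  ``exo_full_degradation``: every
    (start5, start3) of the same enzyme with the 5' site 50-300 nt upstream
    of the 3' site.
    """
    frags: list[ProcessingFragment] = []
    for r5 in rne5_sites:
        for r3 in rne3_sites:
            if not _same_track(r5, r3):
                continue
            d = _tx_distance(r5, r3)
            if 0 < d < rne_max:
                frags.append(ProcessingFragment(r5.contig, r5.strand,
                                                r5.pos, r3.pos, d, "rne_pair"))
    lo, hi = degrade_range
    for enzyme, s5_list in start5_by_enzyme.items():
        for s5 in s5_list:
            for s3 in start3_by_enzyme.get(enzyme, []):
                if not _same_track(s5, s3):
                    continue
                d = _tx_distance(s5, s3)
                if lo <= d <= hi:
                    frags.append(ProcessingFragment(
                        s5.contig, s5.strand, s5.pos, s3.pos, d,
                        "exo_full_degradation", enzyme=enzyme))
    return frags


def rnb_offset_histogram(pairs: list[StopStartPair],
                         max_distance: int = 10,
                         focus: tuple[int, int] = (3, 5),
                         ) -> tuple[dict[int, int], int, float]:
    """Histogram of RNase II trimming distances (1..10 nt).

    Returns the distance -> count map, the number of pairs with distance in
    ``focus`` (default 3-5 nt, the enzyme's footprint offset) and that count
    as a fraction of all pairs.
    """
    hist: dict[int, int] = {}
    n_focus = 0
    total = 0
    for p in pairs:
        if not (0 < p.distance <= max_distance):
            continue
        hist[p.distance] = hist.get(p.distance, 0) + 1
        total += 1
        if focus[0] <= p.distance <= focus[1]:
            n_focus += 1
    fraction = n_focus / total if total else 0.0
    return dict(sorted(hist.items())), n_focus, fraction
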