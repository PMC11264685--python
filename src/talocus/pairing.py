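"""Antitoxin-to-toxin base-pairing repression potential.

The sufficiency rule: a duplex is repression-competent when it contains 15
consecutive Watson-Crick paired positions, or a 17-position window with at
most one internal mismatch (window endpoints must pair).  The scan is a
single-offset antisense slide of the reverse-complemented antitoxin along the
toxin region: no bulges or asymmetric loops.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import Interval, revcomp

CONTIGUOUS_MIN = 15
ONE_MISMATCH_MIN = 17


@dataclass(frozen=True)
class DuplexWindow:
    """One gapless paired window between antitoxin and toxin regions.

    Intervals are on the forward coordinates of the two input strings and have
    equal length.  Mismatch positions are strictly internal (a terminal
    mismatch would simply shorten the window).
    """

    antitoxin_interval: Interval
    toxin_interval: Interval
    length: int
    internal_mismatches: int
    contiguous: bool

    def __post_init__(self) -> None:
        if len(self.antitoxin_interval) != len(self.toxin_interval):
            raise ValueError("paired intervals must have equal length")
        if self.contiguous != (self.internal_mismatches == 0):
            raise ValueError("contiguous flag inconsistent with mismatch count")


@dataclass(frozen=True)
class PairingAssessment:
    antitoxin_id: str
    toxin_id: str
    best_contiguous: DuplexWindow | None
    best_one_mismatch: DuplexWindow | None
    repressive: bool

    @property
    def contiguous_length(self) -> int:
        return self.best_contiguous.length if self.best_contiguous else 0

    @property
    def one_mismatch_length(self) -> int:
        return self.best_one_mismatch.length if self.best_one_mismatch else 0


def _pair_mask(rc_anti: str, toxin: str, offset: int) -> tuple[int, int, list[bool]]:
    """Complementarity mask of rc(antitoxin)[i] vs toxin[offset + i]."""
    la, lt = len(rc_anti), len(toxin)
    i0 = max(0, -offset)
    i1 = min(la, lt - offset)
    mask = [rc_anti[i] == toxin[offset + i] and rc_anti[i] in "ACGT"
            for i in range(i0, i1)]
    return i0, i1, mask


def _wobble_mask(rc_anti: str, toxin: str, offset: int) -> tuple[int, int, list[bool]]:
    la, lt = len(rc_anti), len(toxin)
    i0 = max(0, -offset)
    i1 = min(la, lt - offset)
    mask = []
    for i in range(i0, i1):
        a, t = rc_anti[i], toxin[offset + i]
        wc = a == t and a in "ACGT"
        # G:U wobble: antitoxin G vs toxin T shows as rc 'C' vs 'T';
        # antitoxin T vs toxin G shows as rc 'A' vs 'G'
        wob = (a == "C" and t == "T") or (a == "A" and t == "G")
        mask.append(wc or wob)
    return i0, i1, mask


def best_duplex(antitoxin_region: str, toxin_region: str, *,
                allow_wobble: bool = False
                ) -> tuple[DuplexWindow | None, DuplexWindow | None]:
    """Best contiguous and best one-internal-mismatch duplex windows.

    Exhaustive over every offset of the reverse-complemented antitoxin against
    the toxin region.  The one-mismatch window is the longest window whose
    non-paired positions number at most one and are internal; a fully
    contiguous run therefore also qualifies.
    """
    if not antitoxin_region or not toxin_region:
        raise ValueError("both regions must be non-empty")
    anti = antitoxin_region.upper()
    toxin = toxin_region.upper()
    rc = revcomp(anti)
    la, lt = len(rc), len(toxin)
    mask_fn = _wobble_mask if allow_wobble else _pair_mask

    best_c: tuple[int, int, int] | None = None   # (length, rc_start, offset)
    best_m: tuple[int, int, int, int] | None = None  # (length, rc_start, offset, n_mm)
    for offset in range(-(la - 1), lt):
        i0, i1, mask = mask_fn(rc, toxin, offset)
        if not mask:
            continue
        # maximal runs of consecutive pairs
        runs: list[tuple[int, int]] = []  # (start in rc coords, length)
        k = 0
        while k < len(mask):
            if mask[k]:
                start = k
                while k < len(mask) and mask[k]:
                    k += 1
                runs.append((i0 + start, k - start))
            else:
                k += 1
        for start, length in runs:
            if best_c is None or length > best_c[0]:
                best_c = (length, start, offset)
            if best_m is None or length > best_m[0]:
                best_m = (length, start, offset, 0)
        # join two runs across a single internal mismatch
        for (s1, l1), (s2, l2) in zip(runs, runs[1:]):
            if s2 == s1 + l1 + 1:  # exactly one mismatch between the runs
                length = l1 + 1 + l2
                if best_m is None or length > best_m[0]:
                    best_m = (length, s1, offset, 1)

    def to_window(best, n_mm: int) -> DuplexWindow | None:
        if best is None:
            return None
        length, start, offset = best[:3]
        return DuplexWindow(
            antitoxin_interval=Interval(la - (start + length), la - start),
            toxin_interval=Interval(offset + start, offset + start + length),
            length=length, internal_mismatches=n_mm, contiguous=n_mm == 0)

    win_c = to_window(best_c, 0)
    win_m = to_window(best_m, best_m[3]) if best_m else None
    return win_c, win_m


def is_repressive(best_contiguous: DuplexWindow | None,
                  best_one_mismatch: DuplexWindow | None, *,
                  contiguous_min: int = CONTIGUOUS_MIN,
                  one_mismatch_min: int = ONE_MISMATCH_MIN) -> bool:
    """Sufficiency rule: contiguous >= 15, or one internal mismatch in >= 17."""
    c = best_contiguous.length if best_contiguous else 0
    m = best_one_mismatch.length if best_one_mismatch else 0
    return c >= contiguous_min or m >= one_mismatch_min


def assess(antitoxin_region: str, toxin_region: str, *,
           antitoxin_id: str = "", toxin_id: str = "",
           allow_wobble: bool = False) -> PairingAssessment:
    win_c, win_m = best_duplex(antitoxin_region, toxin_region,
                               allow_wobble=allow_wobble)
    return PairingAssessment(antitoxin_id, toxin_id, win_c, win_m,
                             is_repressive(win_c, win_m))
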