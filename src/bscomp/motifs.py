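"""ACUAA-family motif detection and foreground/background enrichment.

The core branch-site-like motif (default ACTAA after RNA->DNA normalization)
is counted with overlapping occurrences allowed, because tandem-embedded
configurations such as UACUAACUAAC contain two cores that share sequence.
A YAAY "half site" near a single core upgrades it to a bipartite
high-affinity configuration (the SELEX-defined Quaking response element);
half-sites overlapping a core are ignored since every ACUAAC core trivially
contains a YAAY.

Enrichment of dual-core windows in a foreground set against a background set
is tested on the 2x2 contingency table with Pearson chi-squared (optionally
Yates-corrected) or Fisher's exact test.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io_formats import normalize_sequence
from .windows import SeqWindow

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC degenerate DNA pattern; RNA spellings are normalized on input."""

    pattern: str
    name: str = ""

    def __post_init__(self) -> None:
        norm = normalize_sequence(self.pattern)
        object.__setattr__(self, "pattern", norm)
        if not norm:
            raise ValueError("empty motif pattern")
        bad = [c for c in norm if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC character(s) {bad!r} in pattern {norm!r}")

    def __len__(self) -> int:
        return len(self.pattern)


#: named presets for the core motif
CORE_ACTAA = MotifPattern("ACTAA", "ACTAA")
CORE_ACTAAC = MotifPattern("ACTAAC", "ACTAAC")
CORE_TACTAAC = MotifPattern("TACTAAC", "TACTAAC")
HALFSITE_YAAY = MotifPattern("YAAY", "YAAY")


@dataclass
class MotifReport:
    """Motif content of one window: core hits, half-sites, QRE category."""

    intron_id: str
    core_offsets: list[int] = field(default_factory=list)
    halfsite_offsets: list[int] = field(default_factory=list)
    category: str = "none"

    @property
    def core_count(self) -> int:
        return len(self.core_offsets)

    @property
    def is_dual(self) -> bool:
        return self.core_count >= 2


@functools.lru_cache(maxsize=256)
def _compiled(pattern: str) -> re.Pattern:
    # character classes exclude N, so an N in the sequence never matches
    body = "".join(
        c if len(IUPAC_CODES[c]) == 1 else "[" + "".join(sorted(IUPAC_CODES[c])) + "]"
        for c in pattern
    )
    return re.compile(f"(?=({body}))")  # lookahead: overlapping matches


def find_occurrences(seq: str, motif: MotifPattern, overlapping: bool = True) -> list[int]:
    """All start offsets where the IUPAC pattern matches.

    Sequence N never matches any code. With overlapping=False a match may not
    begin inside the previous accepted match.
    """
    hits = [m.start() for m in _compiled(motif.pattern).finditer(seq)]
    if not overlapping:
        filtered: list[int] = []
        last_end = -1
        for h in hits:
            if h > last_end:
                filtered.append(h)
                last_end = h + len(motif) - 1
        hits = filtered
    return hits


def _gap(span_a: tuple[int, int], span_b: tuple[int, int]) -> int:
    """Edge-to-edge gap (intervening nucleotides) between two half-open spans."""
    if span_a[0] >= span_b[1]:
        return span_a[0] - span_b[1]
    if span_b[0] >= span_a[1]:
        return span_b[0] - span_a[1]
    return 0  # overlapping


def classify_window(
    window: SeqWindow | str,
    core: MotifPattern = CORE_ACTAA,
    halfsite: MotifPattern = HALFSITE_YAAY,
    max_dist: int = 20,
    intron_id: str = "",
) -> MotifReport:
    """Classify a window as dual_core, bipartite, core_only or none.

    Half-site hits whose span overlaps any core hit are discarded. A
    half-site qualifies for bipartite status (either side of the core) when
    the edge-to-edge gap to the nearest core hit is <= max_dist. Precedence:
    dual_core > bipartite > core_only.
    """
    if isinstance(window, SeqWindow):
        seq, wid = window.sequence, window.intron_id
    else:
        seq, wid = window, intron_id
    if not seq:
        raise ValueError("empty window sequence")

    core_hits = find_occurrences(seq, core)
    core_spans = [(o, o + len(core)) for o in core_hits]
    half_hits = [
        o
        for o in find_occurrences(seq, halfsite)
        if not any(_gap((o, o + len(halfsite)), cs) == 0 for cs in core_spans)
    ]

    if len(core_hits) >= 2:
        category = "dual_core"
    elif len(core_hits) == 1:
        qualifying = any(
            _gap((o, o + len(halfsite)), core_spans[0]) <= max_dist for o in half_hits
        )
        category = "bipartite" if qualifying else "core_only"
    else:
        category = "none"
    return MotifReport(
        intron_id=wid,
        core_offsets=core_hits,
        halfsite_offsets=half_hits,
        category=category,
    )


def dual_motif_fraction(reports: list[MotifReport]) -> float:
    """Fraction of windows carrying two or more core occurrences."""
    if not reports:
        raise ValueError("no motif reports")
    return sum(r.is_dual for r in reports) / len(reports)


def enrichment_2x2(
    fg_flags: list[bool] | np.ndarray,
    bg_flags: list[bool] | np.ndarray,
    method: str = "chi2",
) -> tuple[float, float, np.ndarray]:
    """Test dual-motif enrichment in foreground vs background windows.

    Builds the table [[fg_dual, fg_not], [bg_dual, bg_not]] and returns
    (statistic, two-sided p, table). Methods: 'chi2' (uncorrected Pearson,
    df=1), 'chi2_yates' (continuity corrected), 'fisher' (exact; statistic is
    the odds ratio). A zero margin is an error for the chi-squared variants.
    """
    fg = np.asarray(fg_flags, dtype=bool)
    bg = np.asarray(bg_flags, dtype=bool)
    if fg.size == 0 or bg.size == 0:
        raise ValueError("both flag sets must be non-empty")
    table = np.array(
        [[int(fg.sum()), int((~fg).sum())], [int(bg.sum()), int((~bg).sum())]]
    )
    if method in ("chi2", "chi2_yates"):
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            raise ValueError("zero margin in 2x2 table; use method='fisher'")
        stat, p, _, _ = stats.chi2_contingency(table, correction=(method == "chi2_yates"))
        return float(stat), float(p), table
    if method == "fisher":
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p), table
    raise ValueError(f"unknown enrichment method {method!r}")
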