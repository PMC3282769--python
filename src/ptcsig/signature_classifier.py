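"""Rule-based discrimination of putrescine vs ornithine transcarbamylases.

Putrescine transcarbamylase (PTC) and ornithine transcarbamylase (OTC)
share the invariant active-site tetrapeptides STRT (carbamylphosphate
binding, position 52 in *E. faecalis* PTC) and HCLP (amine binding,
position 268), which anchor a candidate sequence to the family. Four
traits then discriminate PTC from OTC:

* **lysine_upstream** — OTCs carry a lysine two residues upstream of
  STRT (it ion-pairs the alpha-carboxylate of ornithine); PTCs replace
  it (glutamine in *E. faecalis*).
* **loop230** — roughly 40 residues upstream of HCLP, OTCs have the
  xSMG loop; PTCs replace it with the putrescine-specificity 230-loop
  matching ``(Y/W)(G/W)(V/L/I)X``.
* **cterm_extension** — PTCs extend ~20 residues beyond the OTC
  C-terminus.
* **helix13** — within that extension PTCs carry the helix-13 signature
  ``(L/f/v/i/m)XX(F/Y/L/M/v)(L/i/m)`` in a helix-favoring context
  (the signature marks the trimer-stabilizing C-terminal helix).

``classify`` combines the anchor rule and the four traits into a
verdict with per-rule evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import helix_propensity as hp
from .motif_engine import MotifMatch, MotifPattern, parse_pattern, scan
from .seq_core import SequenceRecord

PTC = "PTC"
OTC = "OTC"
UNCLASSIFIED = "TRANSCARBAMYLASE_UNCLASSIFIED"
NOT_TC = "NOT_TRANSCARBAMYLASE"

PTC_LIKE = "ptc_like"
OTC_LIKE = "otc_like"
ABSENT = "absent"
INAPPLICABLE = "inapplicable"

RULE_IDS = ("anchors", "lysine_upstream", "loop230", "cterm_extension", "helix13")

# Signature notation, kept as the literal strings used in the field.
STRT_PATTERN = "STRT"
HCLP_PATTERN = "HCLP"
HPXQ_PATTERN = "HPXQ"
LOOP_PTC_PATTERN = "(Y/W)(G/W)(V/L/I)X"
LOOP_OTC_PATTERN = "XSMG"
HELIX13_PATTERN = "(L/f/v/i/m)XX(F/Y/L/M/v)(L/i/m)"


@dataclass
class ClassifierConfig:
    """Windows, thresholds and patterns for the five rules.

    Defaults are calibrated on *E. faecalis* PTC numbering: STRT at 52,
    HCLP at 268 (spacing 216), 230-loop starting 38 residues upstream
    of HCLP, C-terminal tail of 69 residues past HCLP.
    """

    anchor_spacing_min: int = 190
    anchor_spacing_max: int = 240
    # 230-loop search: pattern start must fall this many residues
    # upstream of hclp_start (inclusive bounds).
    loop_offset_max: int = 50
    loop_offset_min: int = 28
    cterm_ptc_threshold: int = 60
    cterm_otc_threshold: int = 55
    helix_region_length: int = 30
    propensity_window: int = hp.DEFAULT_WINDOW
    propensity_threshold: float = hp.DEFAULT_THRESHOLD
    strt: str = STRT_PATTERN
    hclp: str = HCLP_PATTERN
    hpxq: str = HPXQ_PATTERN
    loop_ptc: str = LOOP_PTC_PATTERN
    loop_otc: str = LOOP_OTC_PATTERN
    helix13: str = HELIX13_PATTERN

    def __post_init__(self) -> None:
        self._patterns: dict[str, MotifPattern] = {
            name: parse_pattern(getattr(self, name), pattern_id=name)
            for name in ("strt", "hclp", "hpxq", "loop_ptc", "loop_otc", "helix13")
        }

    def pattern(self, name: str) -> MotifPattern:
        return self._patterns[name]


@dataclass
class AnchorSet:
    """Located family anchors (1-based starts; ``None`` when absent)."""

    strt_start: Optional[int] = None
    hclp_start: Optional[int] = None
    hpxq_start: Optional[int] = None

    @property
    def complete(self) -> bool:
        return self.strt_start is not None and self.hclp_start is not None


@dataclass
class RuleOutcome:
    rule_id: str
    status: str
    evidence: dict = field(default_factory=dict)
    note: str = ""


@dataclass
class ClassificationReport:
    record_id: str
    verdict: str
    outcomes: list[RuleOutcome]
    anchors: AnchorSet
    score: int

    def outcome(self, rule_id: str) -> RuleOutcome:
        for o in self.outcomes:
            if o.rule_id == rule_id:
                return o
        raise KeyError(rule_id)


def locate_anchors(seq: SequenceRecord, config: Optional[ClassifierConfig] = None) -> AnchorSet:
    """Find the STRT/HCLP anchor pair with family-consistent spacing.

    Among all STRT and HCLP occurrences, selects the pair whose spacing
    ``hclp_start - strt_start`` lies in the configured window,
    preferring the leftmost STRT then the leftmost HCLP. Absence is a
    value, not an error. The HPXQ motif (shared family evidence) is
    located between the anchors when both are present.
    """
    config = config or ClassifierConfig()
    strt_hits = scan(seq, config.pattern("strt"))
    hclp_hits = scan(seq, config.pattern("hclp"))
    anchors = AnchorSet()
    for s in strt_hits:
        for h in hclp_hits:
            spacing = h.start - s.start
            if config.anchor_spacing_min <= spacing <= config.anchor_spacing_max:
                anchors.strt_start, anchors.hclp_start = s.start, h.start
                break
        if anchors.complete:
            break
    if not anchors.complete:
        # No qualifying pair: report at most one motif so the invariant
        # "both present implies family spacing" holds.
        if strt_hits:
            anchors.strt_start = strt_hits[0].start
        elif hclp_hits:
            anchors.hclp_start = hclp_hits[0].start
    if anchors.complete:
        hpxq = scan(seq, config.pattern("hpxq"), window=(anchors.strt_start, anchors.hclp_start + 3))
        if hpxq:
            anchors.hpxq_start = hpxq[0].start
    return anchors


def rule_anchors(seq: SequenceRecord, anchors: AnchorSet, config: ClassifierConfig) -> RuleOutcome:
    """Family membership: both anchors present with valid spacing."""
    if anchors.complete:
        spacing = anchors.hclp_start - anchors.strt_start
        return RuleOutcome(
            "anchors",
            PTC_LIKE,
            evidence={
                "strt_start": anchors.strt_start,
                "hclp_start": anchors.hclp_start,
                "spacing": spacing,
                "hpxq_start": anchors.hpxq_start,
            },
            note="STRT/HCLP pair found (shared by PTC and OTC)",
        )
    return RuleOutcome(
        "anchors",
        ABSENT,
        evidence={"strt_start": anchors.strt_start, "hclp_start": anchors.hclp_start},
        note="no STRT/HCLP pair with family spacing",
    )


def rule_lysine_upstream(
    seq: SequenceRecord, anchors: AnchorSet, config: Optional[ClassifierConfig] = None
) -> RuleOutcome:
    """OTCs carry K two residues upstream of STRT; PTCs do not."""
    if anchors.strt_start is None or anchors.strt_start < 3:
        return RuleOutcome("lysine_upstream", INAPPLICABLE, note="STRT absent or too close to N-terminus")
    pos = anchors.strt_start - 2
    residue = seq.residue_at(pos)
    status = OTC_LIKE if residue == "K" else PTC_LIKE
    return RuleOutcome(
        "lysine_upstream",
        status,
        evidence={"position": pos, "residue": residue},
        note=f"{residue} at STRT-2",
    )


def rule_230_loop(
    seq: SequenceRecord, anchors: AnchorSet, config: Optional[ClassifierConfig] = None
) -> RuleOutcome:
    """Specificity loop upstream of HCLP: PTC 230-loop vs OTC xSMG."""
    config = config or ClassifierConfig()
    if anchors.hclp_start is None:
        return RuleOutcome("loop230", INAPPLICABLE, note="HCLP absent")
    pat_ptc = config.pattern("loop_ptc")
    pat_otc = config.pattern("loop_otc")
    lo = anchors.hclp_start - config.loop_offset_max
    hi = anchors.hclp_start - config.loop_offset_min + len(pat_ptc) - 1
    if lo < 1 or hi > len(seq):
        return RuleOutcome("loop230", INAPPLICABLE, note="loop window out of sequence bounds")
    ptc_hits = scan(seq, pat_ptc, window=(lo, hi))
    otc_hits = scan(seq, pat_otc, window=(lo, hi))
    evidence = {
        "window": (lo, hi),
        "ptc_matches": [(m.start, m.matched) for m in ptc_hits],
        "otc_matches": [(m.start, m.matched) for m in otc_hits],
    }
    if ptc_hits and not otc_hits:
        return RuleOutcome("loop230", PTC_LIKE, evidence=evidence, note="PTC 230-loop pattern, no xSMG")
    if otc_hits and not ptc_hits:
        return RuleOutcome("loop230", OTC_LIKE, evidence=evidence, note="xSMG loop, no PTC pattern")
    note = "both loop patterns present" if ptc_hits else "neither loop pattern present"
    return RuleOutcome("loop230", ABSENT, evidence=evidence, note=note)


def rule_cterm_extension(
    seq: SequenceRecord, anchors: AnchorSet, config: Optional[ClassifierConfig] = None
) -> RuleOutcome:
    """PTCs extend ~20 residues past the OTC C-terminus (long HCLP tail)."""
    config = config or ClassifierConfig()
    if anchors.hclp_start is None:
        return RuleOutcome("cterm_extension", INAPPLICABLE, note="HCLP absent")
    tail = len(seq) - (anchors.hclp_start + 3)
    evidence = {"tail_length": tail}
    if tail >= config.cterm_ptc_threshold:
        return RuleOutcome("cterm_extension", PTC_LIKE, evidence=evidence, note=f"tail {tail} >= {config.cterm_ptc_threshold}")
    if tail <= config.cterm_otc_threshold:
        return RuleOutcome("cterm_extension", OTC_LIKE, evidence=evidence, note=f"tail {tail} <= {config.cterm_otc_threshold}")
    return RuleOutcome("cterm_extension", ABSENT, evidence=evidence, note=f"tail {tail} in ambiguous band")


def _propensity_window_for_match(match: MotifMatch, seq_len: int, width: int) -> tuple[int, int]:
    """A ``width``-residue window covering the match, clipped to the sequence."""
    center = (match.start + match.end) // 2
    half = width // 2
    lo = center - half
    hi = lo + width - 1
    if lo < 1:
        lo, hi = 1, min(width, seq_len)
    elif hi > seq_len:
        hi, lo = seq_len, max(1, seq_len - width + 1)
    return lo, hi


def rule_helix13(
    seq: SequenceRecord,
    anchors: AnchorSet,
    config: Optional[ClassifierConfig] = None,
    table: Optional[hp.PropensityTable] = None,
) -> RuleOutcome:
    """Helix-13 signature in the C-terminal region, in helix-favoring context."""
    config = config or ClassifierConfig()
    if len(seq) < config.helix_region_length:
        return RuleOutcome("helix13", INAPPLICABLE, note="sequence shorter than C-terminal region")
    region = (len(seq) - config.helix_region_length + 1, len(seq))
    hits = scan(seq, config.pattern("helix13"), window=region)
    if not hits:
        return RuleOutcome("helix13", ABSENT, evidence={"region": region}, note="no helix-13 signature match")
    scores = hp.residue_scores(seq, table)
    passing = []
    evaluated = []
    for m in hits:
        lo, hi = _propensity_window_for_match(m, len(seq), config.propensity_window)
        mean = hp.window_mean(scores, lo, hi)
        evaluated.append((m.start, m.matched, m.primary_fraction, round(mean, 3)))
        if mean > config.propensity_threshold:
            passing.append((m, mean))
    if passing:
        # Prefer strongest (highest primary_fraction), then leftmost.
        best, mean = max(passing, key=lambda t: (t[0].primary_fraction, -t[0].start))
        return RuleOutcome(
            "helix13",
            PTC_LIKE,
            evidence={
                "region": region,
                "match_start": best.start,
                "matched": best.matched,
                "primary_fraction": best.primary_fraction,
                "window_mean_propensity": mean,
            },
            note=f"signature {best.matched} at {best.start}, propensity {mean:.2f}",
        )
    return RuleOutcome(
        "helix13",
        ABSENT,
        evidence={"region": region, "evaluated": evaluated},
        note="signature matches lack helix-favoring context",
    )


def classify(
    seq: SequenceRecord,
    config: Optional[ClassifierConfig] = None,
    table: Optional[hp.PropensityTable] = None,
) -> ClassificationReport:
    """Combine all rules into a PTC/OTC verdict with full evidence.

    Policy: no anchors -> NOT_TRANSCARBAMYLASE; all five rules ptc_like
    -> PTC; anchors present with the three OTC-discriminant rules
    (lysine_upstream, loop230, cterm_extension) otc_like -> OTC;
    anything else -> TRANSCARBAMYLASE_UNCLASSIFIED.
    """
    config = config or ClassifierConfig()
    anchors = locate_anchors(seq, config)
    outcomes = [rule_anchors(seq, anchors, config)]
    if anchors.complete:
        outcomes.append(rule_lysine_upstream(seq, anchors, config))
        outcomes.append(rule_230_loop(seq, anchors, config))
        outcomes.append(rule_cterm_extension(seq, anchors, config))
        outcomes.append(rule_helix13(seq, anchors, config, table))
    else:
        for rid in ("lysine_upstream", "loop230", "cterm_extension", "helix13"):
            outcomes.append(RuleOutcome(rid, INAPPLICABLE, note="anchors absent"))
    score = sum(1 for o in outcomes if o.status == PTC_LIKE)
    status = {o.rule_id: o.status for o in outcomes}
    if not anchors.complete:
        verdict = NOT_TC
    elif all(status[r] == PTC_LIKE for r in RULE_IDS):
        verdict = PTC
    elif all(status[r] == OTC_LIKE for r in ("lysine_upstream", "loop230", "cterm_extension")):
        verdict = OTC
    else:
        verdict = UNCLASSIFIED
    return ClassificationReport(
        record_id=seq.id, verdict=verdict, outcomes=outcomes, anchors=anchors, score=score
    )
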