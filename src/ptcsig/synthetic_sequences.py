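"""Seeded generators for PTC-like and OTC-like fixture sequences.

The generators implant the discriminating traits of each family into a
uniform random amino-acid background, producing sequences on which
every classifier rule is exercisable without any database download:

* PTC-like (default length 340, the *E. faecalis* PTC construct
  length): Q at position 50, STRT at 52, the 230-loop heptapeptide
  DVWYGLY at 227-233, HCLP at 268, and a 69-residue C-terminal tail
  carrying an LAAFL helix-13 signature inside a poly-alanine
  (strongly helix-favoring) stretch.
* OTC-like (default length 320): K at 50, STRT at 52, VSMG at 230-233,
  HCLP at 268, and a short (49-residue) tail with no helix signature.

Backgrounds are rejected and redrawn when they would make a rule
ambiguous: a spurious second anchor, a competing loop motif (or a
second putrescine-loop match) inside the 230 window, or an unintended
helix-13 signature match in the C-terminal region. Fixtures are
therefore unambiguous by construction and every ablation is a
single-trait edit.

Two deliberate layout choices keep ablations single-trait: the helix
context is poly-alanine (alanine is helix-favoring but never matches
the signature's first position, so the implanted LAAFL is the region's
only signature match), and the signature sits near the start of the
tail (default position 312), so the stop-codon-style truncation after
residue 317 used by ``ablate(..., "cterm_extension")`` shortens the
tail without deleting the signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .motif_engine import scan
from .seq_core import SequenceRecord
from .signature_classifier import ClassifierConfig

AA20 = "ACDEFGHIKLMNPQRSTVWY"

PTC_LOOP = "DVWYGLY"   # 227-233 in E. faecalis PTC; YGLY at 230 matches (Y/W)(G/W)(V/L/I)X
OTC_LOOP = "VSMG"      # the OTC xSMG loop counterpart
HELIX13_CORE = "LAAFL"  # satisfies (L/f/v/i/m)XX(F/Y/L/M/v)(L/i/m), all-primary
TRUNCATION_POSITION = 317  # stop codon introduced after this residue

MAX_REDRAWS = 100


class GenerationError(RuntimeError):
    """Raised when a clean background cannot be drawn."""


@dataclass
class FixtureSpec:
    """Parameters of a generated fixture.

    Positions are 1-based and follow *E. faecalis* PTC numbering; the
    defaults reproduce that enzyme's trait layout.
    """

    seed: int = 1
    length: int = 340
    strt_pos: int = 52
    hclp_pos: int = 268
    loop_variant: str = "ptc"  # "ptc" or "otc"
    upstream_residue: str = "Q"
    tail_signature: bool = True
    helix_sig_pos: int = 312
    helix_context: tuple[int, int] = (302, 320)

    def __post_init__(self) -> None:
        if not (self.strt_pos + 190 <= self.hclp_pos <= self.strt_pos + 240):
            raise ValueError("anchor spacing outside family window")
        if self.hclp_pos + 3 > self.length:
            raise ValueError("HCLP does not fit in sequence")
        if self.loop_variant not in ("ptc", "otc"):
            raise ValueError(f"unknown loop_variant {self.loop_variant!r}")


def ptc_default_spec(seed: int = 1) -> FixtureSpec:
    return FixtureSpec(seed=seed)


def otc_default_spec(seed: int = 1) -> FixtureSpec:
    return FixtureSpec(
        seed=seed,
        length=320,
        loop_variant="otc",
        upstream_residue="K",
        tail_signature=False,
    )


def _implant(residues: list[str], pos: int, text: str) -> None:
    residues[pos - 1 : pos - 1 + len(text)] = list(text)


def _loop_pos(spec: FixtureSpec) -> int:
    # PTC heptapeptide at 227 puts YGLY at 230 (38 upstream of HCLP at
    # 268); the OTC tetrapeptide sits at 230 directly.
    return (spec.hclp_pos - 41) if spec.loop_variant == "ptc" else (spec.hclp_pos - 38)


def _clean(seq_str: str, spec: FixtureSpec, config: ClassifierConfig) -> bool:
    """Acceptance check run on the fully implanted candidate sequence."""
    # Exactly one STRT and one HCLP, at the intended anchor positions.
    if seq_str.count("STRT") != 1 or seq_str.find("STRT") != spec.strt_pos - 1:
        return False
    if seq_str.count("HCLP") != 1 or seq_str.find("HCLP") != spec.hclp_pos - 1:
        return False
    rec = SequenceRecord(id="candidate", residues=seq_str)
    lo = spec.hclp_pos - config.loop_offset_max
    hi = spec.hclp_pos - config.loop_offset_min + 3
    ptc_hits = scan(rec, config.pattern("loop_ptc"), window=(lo, hi))
    if spec.loop_variant == "ptc":
        # Only the implanted YGLY may match, and no xSMG anywhere in the
        # window (so the loop-swap ablation flips cleanly to otc_like).
        if "SMG" in seq_str[lo - 1 : hi]:
            return False
        if [m.start for m in ptc_hits] != [_loop_pos(spec) + 3]:
            return False
    else:
        if ptc_hits:
            return False
    # C-terminal region: only the implanted helix signature may match.
    region = (len(seq_str) - config.helix_region_length + 1, len(seq_str))
    sig_hits = [m.start for m in scan(rec, config.pattern("helix13"), window=region)]
    expected = [spec.helix_sig_pos] if spec.tail_signature else []
    if sig_hits != expected:
        return False
    return True


def _generate(spec: FixtureSpec, record_id: str, config: Optional[ClassifierConfig] = None) -> SequenceRecord:
    config = config or ClassifierConfig()
    rng = np.random.default_rng(spec.seed)
    loop = PTC_LOOP if spec.loop_variant == "ptc" else OTC_LOOP
    loop_pos = _loop_pos(spec)
    for _ in range(MAX_REDRAWS):
        residues = [AA20[i] for i in rng.integers(0, 20, size=spec.length)]
        _implant(residues, spec.strt_pos - 2, spec.upstream_residue)
        _implant(residues, spec.strt_pos, "STRT")
        _implant(residues, loop_pos, loop)
        _implant(residues, spec.hclp_pos, "HCLP")
        if spec.tail_signature:
            ctx_lo, ctx_hi = spec.helix_context
            _implant(residues, ctx_lo, "A" * (ctx_hi - ctx_lo + 1))
            _implant(residues, spec.helix_sig_pos, HELIX13_CORE)
        seq_str = "".join(residues)
        if _clean(seq_str, spec, config):
            rec = SequenceRecord(id=record_id, residues=seq_str)
            rec.annotations["fixture_spec"] = spec
            rec.annotations["implants"] = {
                "upstream": spec.strt_pos - 2,
                "strt": spec.strt_pos,
                "loop": loop_pos,
                "hclp": spec.hclp_pos,
                "helix13": spec.helix_sig_pos if spec.tail_signature else None,
            }
            return rec
    raise GenerationError(f"no clean background after {MAX_REDRAWS} redraws (seed {spec.seed})")


def generate_ptc_like(spec: Optional[FixtureSpec] = None, *, seed: Optional[int] = None) -> SequenceRecord:
    """Generate a sequence carrying all five PTC traits."""
    if spec is None:
        spec = ptc_default_spec(seed if seed is not None else 1)
    return _generate(spec, record_id=f"ptc_like_seed{spec.seed}")


def generate_otc_like(spec: Optional[FixtureSpec] = None, *, seed: Optional[int] = None) -> SequenceRecord:
    """Generate a sequence carrying the OTC-discriminant traits."""
    if spec is None:
        spec = otc_default_spec(seed if seed is not None else 1)
    return _generate(spec, record_id=f"otc_like_seed{spec.seed}")


def ablate(record: SequenceRecord, rule_id: str) -> SequenceRecord:
    """Minimal edit pushing exactly one rule toward its OTC/absent state.

    Edits are idempotent: re-ablating an already ablated record leaves
    the classification unchanged.

    * ``lysine_upstream`` — replace the residue two upstream of STRT by K.
    * ``loop230`` — replace the implanted YGLY by VSMG (the engineered
      loop-swap construct).
    * ``cterm_extension`` — truncate after residue 317 (the stop-codon
      construct that removes the long C-terminal tail).
    * ``helix13`` — overwrite the signature core with poly-alanine,
      erasing the motif while keeping the context helix-favoring.
    """
    implants = record.annotations.get("implants")
    if implants is None:
        raise ValueError("ablate requires a generator-produced record (implant map missing)")
    residues = list(record.residues)
    if rule_id == "lysine_upstream":
        residues[implants["upstream"] - 1] = "K"
    elif rule_id == "loop230":
        start = implants["loop"] + 3  # YGLY offset inside DVWYGLY
        if residues[start - 1 : start + 3] == list("YGLY"):
            residues[start - 1 : start + 3] = list("VSMG")
    elif rule_id == "cterm_extension":
        residues = residues[:TRUNCATION_POSITION]
    elif rule_id == "helix13":
        sig = implants.get("helix13")
        if sig is not None and residues[sig - 1 : sig + 4] == list(HELIX13_CORE):
            residues[sig - 1 : sig + 4] = list("AAAAA")
    else:
        raise ValueError(f"unknown rule_id {rule_id!r}")
    out = SequenceRecord(
        id=f"{record.id}_ablate_{rule_id}",
        residues="".join(residues),
        annotations=dict(record.annotations),
    )
    out.annotations["ablated"] = record.annotations.get("ablated", ()) + (rule_id,)
    return out
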