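"""ST-elevation pattern taxonomy and composable diagnostic criteria.

Three main patterns describe the ECG of acute total left main (LM)
occlusion:

* ``STEMI`` — ST elevation in contiguous leads (precordial chain,
  inferior leads, or lateral leads with V5/V6);
* ``AVR_PATTERN`` — STE confined to aVR (or aVR and V1) with diffuse
  ST depression, the signature of global subendocardial ischemia;
* ``AVR_AVL_PATTERN`` — STE in both aVR and aVL (or I, aVL and aVR)
  without lateral precordial elevation.

A finer taxonomy subdivides these into the mutually exclusive lead-set
patterns observed in LM occlusion (e.g. STE in I, aVL and V2-V5 without
V1). On top of the taxonomy sit named Boolean criteria, including the two
combined models:

* Model 1 = STE in both aVR and aVL, OR STE in I, aVL, V2-V5 without V1
  (and without aVR);
* Model 2 = Model 1 AND left anterior fascicular block (with or without
  RBBB).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .feature_model import (
    ECGFeatureRecord,
    INFERIOR,
    LEADS,
    Lead,
    PRECORDIAL,
    is_ste,
    ste_lead_set,
)

__all__ = [
    "MainPattern",
    "FinePattern",
    "FINE_TO_MAIN",
    "classify_main",
    "classify_fine",
    "Criterion",
    "CriterionRegistry",
    "builtin_criteria",
    "criterion_from_expression",
    "model1",
    "model2",
    "evaluate_criterion",
]


class MainPattern(enum.Enum):
    STEMI = "stemi"
    AVR_PATTERN = "avr"
    AVR_AVL_PATTERN = "avr_avl"
    OTHER_NSTEMI = "other_nstemi"


class FinePattern(enum.Enum):
    P_I_AVL_V2_V5 = "i_avl_v2_v5"
    P_I_AVL_V1_V5 = "i_avl_v1_v5"
    P_V1_V5 = "v1_v5"
    P_V2_V5 = "v2_v5"
    P_AVR_AVL = "avr_avl"
    P_I_AVL_AVR = "i_avl_avr"
    P_AVR_AVL_PARTIAL_PRECORDIAL = "avr_avl_partial_precordial"
    P_AVR = "avr"
    P_AVR_V1 = "avr_v1"
    P_INFERIOR = "inferior"
    P_OTHER_STEMI = "other_stemi"
    P_OTHER_NSTEMI = "other_nstemi"


#: Projection of the fine taxonomy onto the main patterns.
FINE_TO_MAIN: dict[FinePattern, MainPattern] = {
    FinePattern.P_I_AVL_V2_V5: MainPattern.STEMI,
    FinePattern.P_I_AVL_V1_V5: MainPattern.STEMI,
    FinePattern.P_V1_V5: MainPattern.STEMI,
    FinePattern.P_V2_V5: MainPattern.STEMI,
    FinePattern.P_INFERIOR: MainPattern.STEMI,
    FinePattern.P_OTHER_STEMI: MainPattern.STEMI,
    FinePattern.P_AVR: MainPattern.AVR_PATTERN,
    FinePattern.P_AVR_V1: MainPattern.AVR_PATTERN,
    FinePattern.P_AVR_AVL: MainPattern.AVR_AVL_PATTERN,
    FinePattern.P_I_AVL_AVR: MainPattern.AVR_AVL_PATTERN,
    FinePattern.P_AVR_AVL_PARTIAL_PRECORDIAL: MainPattern.AVR_AVL_PATTERN,
    FinePattern.P_OTHER_NSTEMI: MainPattern.OTHER_NSTEMI,
}


def _stemi_rule(s: frozenset[Lead]) -> bool:
    """Contiguity rule for STEMI.

    STE in >= 2 adjacent leads of the precordial chain V1..V6, or in >= 2
    of {II, III, aVF}, or in (V5 or V6) together with (I or aVL).
    """
    for a, b in zip(PRECORDIAL, PRECORDIAL[1:]):
        if a in s and b in s:
            return True
    if sum(ld in s for ld in INFERIOR) >= 2:
        return True
    if (Lead.V5 in s or Lead.V6 in s) and (Lead.I in s or Lead.aVL in s):
        return True
    return False


def classify_main(record: ECGFeatureRecord) -> MainPattern:
    """Assign the record's main pattern (total, deterministic).

    Priority: aVR pattern (STE confined to {aVR, V1}, aVR elevated), then
    aVR+aVL pattern (both elevated, no STE in V4-V6, contiguity rule not
    met), then STEMI by the contiguity rule, else OTHER_NSTEMI.
    """
    s = ste_lead_set(record)
    if Lead.aVR in s and s <= {Lead.aVR, Lead.V1}:
        return MainPattern.AVR_PATTERN
    if (
        Lead.aVR in s
        and Lead.aVL in s
        and not s & {Lead.V4, Lead.V5, Lead.V6}
        and not _stemi_rule(s)
    ):
        return MainPattern.AVR_AVL_PATTERN
    if _stemi_rule(s):
        return MainPattern.STEMI
    return MainPattern.OTHER_NSTEMI


_V1_V5 = frozenset({Lead.V1, Lead.V2, Lead.V3, Lead.V4, Lead.V5})
_V2_V5 = frozenset({Lead.V2, Lead.V3, Lead.V4, Lead.V5})


def classify_fine(record: ECGFeatureRecord) -> FinePattern:
    """Assign the record's fine pattern (first match in fixed priority).

    The aVR+aVL "partial precordial" variant is recognised before the plain
    aVR+aVL family members: within the aVR+aVL main pattern it additionally
    requires anterior involvement — qualifying STE in V2/V3, or
    sub-threshold anterior elevation of at least 0.5 mm in V2 or V3.
    Sub-threshold anterior elevation is what distinguishes the
    collateralised aVR+aVL variant whose V2-V3 elevation does not reach the
    sex-specific threshold.
    """
    s = ste_lead_set(record)
    main = classify_main(record)
    lateral = {Lead.V4, Lead.V5, Lead.V6}

    if _V1_V5 <= s and Lead.I in s and Lead.aVL in s and Lead.aVR not in s:
        return FinePattern.P_I_AVL_V1_V5
    if (
        _V2_V5 <= s
        and Lead.I in s
        and Lead.aVL in s
        and Lead.V1 not in s
        and Lead.aVR not in s
    ):
        return FinePattern.P_I_AVL_V2_V5
    if _V1_V5 <= s and not s & {Lead.I, Lead.aVL, Lead.aVR}:
        return FinePattern.P_V1_V5
    if _V2_V5 <= s and not s & {Lead.V1, Lead.I, Lead.aVL, Lead.aVR}:
        return FinePattern.P_V2_V5
    if s == {Lead.aVR, Lead.V1}:
        return FinePattern.P_AVR_V1
    if s == {Lead.aVR}:
        return FinePattern.P_AVR
    if Lead.aVR in s and Lead.aVL in s and main is MainPattern.AVR_AVL_PATTERN:
        anterior = s & {Lead.V2, Lead.V3} or (
            max(record.st[Lead.V2], record.st[Lead.V3]) >= 0.5
        )
        if anterior:
            return FinePattern.P_AVR_AVL_PARTIAL_PRECORDIAL
    if (
        Lead.I in s
        and Lead.aVL in s
        and Lead.aVR in s
        and not s & lateral
        and main is not MainPattern.STEMI
    ):
        return FinePattern.P_I_AVL_AVR
    if (
        Lead.aVR in s
        and Lead.aVL in s
        and Lead.I not in s
        and not s & lateral
        and main is not MainPattern.STEMI
    ):
        return FinePattern.P_AVR_AVL
    if sum(ld in s for ld in INFERIOR) >= 2:
        return FinePattern.P_INFERIOR
    if main is MainPattern.STEMI:
        return FinePattern.P_OTHER_STEMI
    return FinePattern.P_OTHER_NSTEMI


# ---------------------------------------------------------------------------
# Criteria


@dataclass(frozen=True)
class Criterion:
    """A named, pure Boolean rule over an ECG feature record."""

    name: str
    predicate: Callable[[ECGFeatureRecord], bool]
    description: str = ""

    def __call__(self, record: ECGFeatureRecord) -> bool:
        return bool(self.predicate(record))


class CriterionRegistry(dict):
    """Name -> Criterion mapping that rejects duplicate registration."""

    def register(self, criterion: Criterion) -> Criterion:
        if criterion.name in self:
            raise ValueError(f"duplicate criterion name: {criterion.name}")
        self[criterion.name] = criterion
        return criterion


def _avr_avl(r: ECGFeatureRecord) -> bool:
    # Permissive lead-pair rule: both aVR and aVL elevated, any other leads
    # allowed. This is the reading under which the LM-occlusion row count 23
    # equals the 13 + 8 + 2 fine-pattern decomposition.
    return is_ste(r, Lead.aVR) and is_ste(r, Lead.aVL)


def _i_avl_v2_v5(r: ECGFeatureRecord) -> bool:
    # STE in I, aVL and the whole V2-V5 chain, without V1 and without aVR.
    # Excluding aVR makes this disjoint from the aVR+aVL rule, so the two
    # Model-1 components partition its positives.
    s = ste_lead_set(r)
    return (
        _V2_V5 <= s
        and Lead.I in s
        and Lead.aVL in s
        and Lead.V1 not in s
        and Lead.aVR not in s
    )


def model1(record: ECGFeatureRecord) -> bool:
    """Combined STE criteria: aVR+aVL elevation OR I, aVL, V2-V5 without V1."""
    return _avr_avl(record) or _i_avl_v2_v5(record)


def model2(record: ECGFeatureRecord) -> bool:
    """Model 1 AND left anterior fascicular block (isolated or with RBBB)."""
    return model1(record) and record.conduction.lafb


def builtin_criteria() -> CriterionRegistry:
    """Registry of the named built-in criteria.

    Exclusive fine-pattern criteria (``avr_isolated``, ``avr_v1``) coexist
    with permissive lead-pair criteria (``avr_avl``): the former count a
    record only when its whole STE set matches the pattern, the latter
    whenever the named leads are elevated.
    """
    reg = CriterionRegistry()
    fine = classify_fine
    main = classify_main

    def add(name, pred, desc=""):
        reg.register(Criterion(name, pred, desc))

    add("avr_isolated", lambda r: fine(r) is FinePattern.P_AVR,
        "STE confined to aVR (exclusive pattern)")
    add("avr_v1", lambda r: fine(r) is FinePattern.P_AVR_V1,
        "STE confined to aVR and V1 (exclusive pattern)")
    add("avr_any_isolated",
        lambda r: fine(r) in (FinePattern.P_AVR, FinePattern.P_AVR_V1),
        "STE confined to aVR, optionally with V1")
    add("avr_avl", _avr_avl, "STE in both aVR and aVL (any other leads allowed)")
    add("i_avl_v2_v5", _i_avl_v2_v5,
        "STE in I, aVL and V2-V5, without V1 and without aVR")
    add("i_avl_v1_v5", lambda r: fine(r) is FinePattern.P_I_AVL_V1_V5,
        "STE in I, aVL and V1-V5")
    add("v1_v5", lambda r: fine(r) is FinePattern.P_V1_V5,
        "STE in V1-V5 without I/aVL/aVR")
    add("v2_v5", lambda r: fine(r) is FinePattern.P_V2_V5,
        "STE in V2-V5 without V1/I/aVL/aVR")
    add("inferior", lambda r: fine(r) is FinePattern.P_INFERIOR,
        "STE in at least two of II, III, aVF")
    add("stemi", lambda r: main(r) is MainPattern.STEMI, "STEMI main pattern")
    add("nstemi", lambda r: main(r) is not MainPattern.STEMI,
        "any non-STEMI main pattern")
    add("lafb", lambda r: r.conduction.lafb and not r.conduction.rbbb,
        "isolated left anterior fascicular block")
    add("rbbb", lambda r: r.conduction.rbbb and not r.conduction.lafb,
        "isolated right bundle branch block")
    add("lbbb", lambda r: r.conduction.lbbb, "left bundle branch block")
    add("hdavb", lambda r: r.conduction.hdavb,
        "high-degree atrioventricular block")
    add("bifascicular", lambda r: r.conduction.lafb and r.conduction.rbbb,
        "LAFB + RBBB")
    add("lafb_any", lambda r: r.conduction.lafb,
        "LAFB with or without RBBB")
    add("avr_avl_lafb",
        lambda r: _avr_avl(r) and r.conduction.lafb and not r.conduction.rbbb,
        "STE in aVR+aVL plus isolated LAFB")
    add("avr_avl_bifascicular",
        lambda r: _avr_avl(r) and r.conduction.lafb and r.conduction.rbbb,
        "STE in aVR+aVL plus LAFB + RBBB")
    add("i_avl_v2_v5_lafb",
        lambda r: _i_avl_v2_v5(r) and r.conduction.lafb and not r.conduction.rbbb,
        "STE in I, aVL, V2-V5 plus isolated LAFB")
    add("i_avl_v2_v5_bifascicular",
        lambda r: _i_avl_v2_v5(r) and r.conduction.lafb and r.conduction.rbbb,
        "STE in I, aVL, V2-V5 plus LAFB + RBBB")
    add("model1", model1,
        "STE in aVR+aVL, or STE in I, aVL, V2-V5 without V1")
    add("model2", model2, "Model 1 plus LAFB (with or without RBBB)")
    return reg


# ---------------------------------------------------------------------------
# Expression-tree criteria (for config files)

_ATOMS = ("ste", "no_ste", "flag", "main")
_FLAGS = ("lafb", "rbbb", "lbbb", "hdavb", "bifascicular")


def _compile_expression(expr) -> Callable[[ECGFeatureRecord], bool]:
    """Compile a nested {op: args} mapping into a predicate.

    Vocabulary: ``{"ste": "aVL"}``, ``{"no_ste": "V1"}``,
    ``{"flag": "lafb"}``, ``{"main": "stemi"}``, combined with
    ``{"and": [...]}, {"or": [...]}, {"not": ...}``.
    """
    if not isinstance(expr, Mapping) or len(expr) != 1:
        raise ValueError(f"criterion expression must be a single-key mapping: {expr!r}")
    (op, arg), = expr.items()
    if op == "and":
        subs = [_compile_expression(e) for e in arg]
        return lambda r: all(p(r) for p in subs)
    if op == "or":
        subs = [_compile_expression(e) for e in arg]
        return lambda r: any(p(r) for p in subs)
    if op == "not":
        sub = _compile_expression(arg)
        return lambda r: not sub(r)
    if op == "ste" or op == "no_ste":
        try:
            lead = Lead(arg)
        except ValueError:
            raise ValueError(f"unknown lead in expression: {arg!r}") from None
        if op == "ste":
            return lambda r: is_ste(r, lead)
        return lambda r: not is_ste(r, lead)
    if op == "flag":
        if arg not in _FLAGS:
            raise ValueError(f"unknown conduction flag: {arg!r}")
        if arg == "bifascicular":
            return lambda r: r.conduction.lafb and r.conduction.rbbb
        return lambda r: getattr(r.conduction, arg)
    if op == "main":
        pattern = MainPattern(arg)
        return lambda r: classify_main(r) is pattern
    raise ValueError(f"unknown operator in criterion expression: {op!r}")


def criterion_from_expression(name: str, expr) -> Criterion:
    """Build a named Criterion from a nested Boolean expression."""
    return Criterion(name, _compile_expression(expr), "user-defined expression")


def evaluate_criterion(
    criterion: Criterion | str,
    records: Sequence[ECGFeatureRecord],
    registry: CriterionRegistry | None = None,
) -> list[bool]:
    """Element-wise, order-preserving evaluation of a criterion."""
    if isinstance(criterion, str):
        reg = builtin_criteria() if registry is None else registry
        if criterion not in reg:
            raise KeyError(f"unregistered criterion: {criterion!r}")
        criterion = reg[criterion]
    return [criterion(r) for r in records]
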