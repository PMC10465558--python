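"""The rule engine: feature/threshold conditions that remove unreliable PSMs.

A PSM is removed when *any* configured condition fires.  The nine default
conditions target PSMs whose reporter ratios tend to be inaccurate (high
charge, heavy precursor, long peptide, weak reporter signal, outlying
ratio distances) or whose identification is doubtful (large mass error,
low library dot product, low discriminant F-value):

    charge                 >= 5
    precursor_mass_da      >= 4000 Da
    peptide_length         >= 25
    avg_reporter_intensity <  10000
    ipepdist               >= 0.8
    iprotdist              >= 0.6
    abs_mass_diff_da       >= 2 Da
    sl_dot                 <  0.4
    f_value                <  0.4

Conditions on features a PSM does not have (missing reporters, no
spectral-library scores) are bypassed — recorded, never triggered.
Comparators follow the printed inequalities exactly: ``>=`` conditions
remove boundary values, ``<`` conditions retain them.

In the combined database + spectral-library (DB + SL) workflow, only PSMs
found *exclusively* by the combined search are filtered; PSMs already
identified by database searching alone are the quantitation baseline and
pass through untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Set

from .features import FEATURE_NAMES, FeatureVector
from .model import ChannelDesign, Psm, SpectrumKey

__all__ = [
    "Condition",
    "FilterConfig",
    "FilterDecision",
    "ExclusiveFilterResult",
    "apply_filter",
    "filter_exclusive",
]

#: Default direction for the features carrying a published cutoff; used when
#: a config file gives a bare threshold number.
DEFAULT_COMPARATORS = {
    "charge": "ge",
    "precursor_mass_da": "ge",
    "peptide_length": "ge",
    "avg_reporter_intensity": "lt",
    "ipepdist": "ge",
    "iprotdist": "ge",
    "abs_mass_diff_da": "ge",
    "sl_dot": "lt",
    "f_value": "lt",
}


@dataclass(frozen=True)
class Condition:
    """One removal rule: ``feature <comparator> threshold`` removes the PSM."""

    feature: str
    comparator: str  # "ge" (>=) or "lt" (<)
    threshold: float

    def __post_init__(self) -> None:
        if self.feature not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.feature!r}")
        if self.comparator not in ("ge", "lt"):
            raise ValueError(f"comparator must be 'ge' or 'lt', got {self.comparator!r}")
        if not (self.threshold == self.threshold and abs(self.threshold) != float("inf")):
            raise ValueError("threshold must be finite")

    def triggers(self, value: float) -> bool:
        if self.comparator == "ge":
            return value >= self.threshold
        return value < self.threshold


def default_conditions() -> tuple[Condition, ...]:
    return (
        Condition("charge", "ge", 5),
        Condition("precursor_mass_da", "ge", 4000),
        Condition("peptide_length", "ge", 25),
        Condition("avg_reporter_intensity", "lt", 10000),
        Condition("ipepdist", "ge", 0.8),
        Condition("iprotdist", "ge", 0.6),
        Condition("abs_mass_diff_da", "ge", 2),
        Condition("sl_dot", "lt", 0.4),
        Condition("f_value", "lt", 0.4),
    )


@dataclass(frozen=True)
class FilterConfig:
    """The set of active conditions; defaults to the nine standard rules."""

    conditions: tuple[Condition, ...] = field(default_factory=default_conditions)

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        seen = set()
        for c in self.conditions:
            if c.feature in seen:
                raise ValueError(f"duplicate condition on feature {c.feature!r}")
            seen.add(c.feature)

    @classmethod
    def from_toml(cls, path) -> "FilterConfig":
        """Read conditions from a TOML file.

        Under ``[conditions]``, a bare number uses the feature's standard
        comparator; a table ``{op = "ge"|"lt", threshold = x}`` sets both.
        Features omitted from the file have no condition.
        """
        import tomllib

        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        conds = []
        for feature, value in doc.get("conditions", {}).items():
            if isinstance(value, Mapping):
                conds.append(Condition(feature, str(value["op"]), float(value["threshold"])))
            else:
                if feature not in DEFAULT_COMPARATORS:
                    raise ValueError(
                        f"feature {feature!r} has no default comparator; "
                        "use {op = ..., threshold = ...}"
                    )
                conds.append(Condition(feature, DEFAULT_COMPARATORS[feature], float(value)))
        return cls(conditions=tuple(conds))


@dataclass(frozen=True)
class FilterDecision:
    """Per-PSM verdict with the conditions that fired or were bypassed."""

    key: SpectrumKey
    removed: bool
    triggered: tuple[str, ...]
    bypassed: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.removed != (len(self.triggered) > 0):
            raise ValueError("removed must equal bool(triggered)")


def apply_filter(
    features: Mapping[SpectrumKey, FeatureVector], config: FilterConfig | None = None
) -> list[FilterDecision]:
    """Evaluate every condition on every PSM; any hit removes the PSM.

    Conditions whose feature is missing for a PSM are bypassed for that PSM
    and listed in the decision's ``bypassed`` field.
    """
    if config is None:
        config = FilterConfig()
    decisions = []
    for key, fv in features.items():
        triggered, bypassed = [], []
        for cond in config.conditions:
            value = getattr(fv, cond.feature)
            if value is None:
                bypassed.append(cond.feature)
            elif cond.triggers(value):
                triggered.append(cond.feature)
        decisions.append(
            FilterDecision(
                key=key,
                removed=bool(triggered),
                triggered=tuple(triggered),
                bypassed=tuple(bypassed),
            )
        )
    return decisions


@dataclass(frozen=True)
class ExclusiveFilterResult:
    """Outcome of filtering only the DB + SL-exclusive PSMs.

    ``retained`` = common PSMs (untouched) + exclusive PSMs that passed;
    ``removed`` = exclusive PSMs that triggered a condition.
    """

    retained: tuple[Psm, ...]
    removed: tuple[Psm, ...]
    common_keys: frozenset[SpectrumKey]
    decisions: tuple[FilterDecision, ...]


def filter_exclusive(
    db_keys: Set[SpectrumKey],
    dbsl_psms: Sequence[Psm],
    design: ChannelDesign,
    config: FilterConfig | None = None,
) -> ExclusiveFilterResult:
    """Apply the filter to DB + SL-exclusive PSMs only.

    PSMs whose key also appears in the database-search result are the
    baseline and are retained regardless of their features.
    """
    from .features import featurize

    exclusive = [p for p in dbsl_psms if p.key not in db_keys]
    common = [p for p in dbsl_psms if p.key in db_keys]
    feats = featurize(exclusive, design)
    decisions = apply_filter(feats, config)
    removed_keys = {d.key for d in decisions if d.removed}
    retained = common + [p for p in exclusive if p.key not in removed_keys]
    removed = [p for p in exclusive if p.key in removed_keys]
    return ExclusiveFilterResult(
        retained=tuple(retained),
        removed=tuple(removed),
        common_keys=frozenset(p.key for p in common),
        decisions=tuple(decisions),
    )
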