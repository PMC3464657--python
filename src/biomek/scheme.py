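"""Meta-knowledge annotation scheme: dimensions, legal values, defaults.

Five dimensions are assigned per event, each with exactly one value.  Two
binary hyper-dimensions (new knowledge, hypothesis) are derived from
combinations of the assigned values via a configurable rule table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

#: Dimension tags in canonical order.
DIMENSIONS: tuple[str, ...] = ("KT", "CL", "Polarity", "Manner", "Source")

#: Legal values per dimension, default value first.  The ordering doubles as
#: the deterministic tie-break order for classifier argmax decisions.
VALUES: dict[str, tuple[str, ...]] = {
    "KT": ("Other", "Investigation", "Observation", "Analysis", "Fact", "Method"),
    "CL": ("L3", "L2", "L1"),
    "Polarity": ("Positive", "Negative"),
    "Manner": ("Neutral", "High", "Low"),
    "Source": ("Current", "Other"),
}

#: Default value per dimension (assigned absent explicit evidence).
DEFAULTS: dict[str, str] = {dim: VALUES[dim][0] for dim in DIMENSIONS}


def is_legal(dimension: str, value: str) -> bool:
    """True if ``value`` is a legal label of ``dimension``."""
    return dimension in VALUES and value in VALUES[dimension]


def n_values() -> int:
    """Total count of (dimension, value) pairs in the scheme."""
    return sum(len(v) for v in VALUES.values())


@dataclass
class MetaKnowledge:
    """One value per dimension plus optional cue references and derived flags.

    ``cues`` maps a dimension tag to the ids of text-bound cue annotations
    supporting its value (empty when the value is a default or no cue is
    recorded).
    """

    kt: str = DEFAULTS["KT"]
    cl: str = DEFAULTS["CL"]
    polarity: str = DEFAULTS["Polarity"]
    manner: str = DEFAULTS["Manner"]
    source: str = DEFAULTS["Source"]
    cues: dict[str, list[str]] = field(default_factory=dict)
    new_knowledge: str | None = None
    hypothesis: str | None = None

    _FIELD_BY_DIM = {
        "KT": "kt",
        "CL": "cl",
        "Polarity": "polarity",
        "Manner": "manner",
        "Source": "source",
    }

    def value(self, dimension: str) -> str:
        return getattr(self, self._FIELD_BY_DIM[dimension])

    def set_value(self, dimension: str, value: str) -> None:
        if not is_legal(dimension, value):
            raise ValueError(f"illegal value {value!r} for dimension {dimension}")
        setattr(self, self._FIELD_BY_DIM[dimension], value)

    def as_dict(self) -> dict[str, str]:
        return {dim: self.value(dim) for dim in DIMENSIONS}

    def copy(self) -> "MetaKnowledge":
        return replace(self, cues={d: list(v) for d, v in self.cues.items()})

    def validate(self) -> None:
        for dim in DIMENSIONS:
            if not is_legal(dim, self.value(dim)):
                raise ValueError(
                    f"illegal value {self.value(dim)!r} for dimension {dim}"
                )


# ---------------------------------------------------------------------------
# Hyper-dimension rule tables.
#
# The contributing dimensions are fixed by the scheme (hypothesis from KT and
# CL; new knowledge from KT, Source and CL) but the exact rules are
# configuration.  The defaults below encode: a hypothesis is an enquiry or an
# uncertain analysis; new knowledge is a confident observation/analysis made
# in the current study.

HyperRule = Callable[[MetaKnowledge], bool]


def _default_hypothesis(mk: MetaKnowledge) -> bool:
    return mk.kt == "Investigation" or (mk.kt == "Analysis" and mk.cl in ("L1", "L2"))


def _default_new_knowledge(mk: MetaKnowledge) -> bool:
    return mk.source == "Current" and mk.cl == "L3" and mk.kt in ("Observation", "Analysis")


DEFAULT_HYPER_RULES: Mapping[str, HyperRule] = {
    "hypothesis": _default_hypothesis,
    "new_knowledge": _default_new_knowledge,
}


def derive_hyperdimensions(
    mk: MetaKnowledge, rules: Mapping[str, HyperRule] = DEFAULT_HYPER_RULES
) -> tuple[str, str]:
    """Return ``(new_knowledge, hypothesis)`` flags, each "Yes" or "No"."""
    mk.validate()
    new = "Yes" if rules["new_knowledge"](mk) else "No"
    hyp = "Yes" if rules["hypothesis"](mk) else "No"
    return new, hyp
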