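"""Result containers shared across the metric modules.

Metrics on noisy trial data are not always defined: the signal-power
estimate can be non-positive on unreliable units, predictions can be
constant, split-half correlations can come out negative. Rather than
raising mid-batch or silently propagating NaN, every metric returns a
:class:`MetricValue` whose ``value`` is ``None`` when undefined and whose
``flags`` say why (or carry warnings on values that are defined but
suspect).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Tuple

# Undefined-metric flags
SP_NONPOSITIVE = "SP_NONPOSITIVE"
CONSTANT_PREDICTION = "CONSTANT_PREDICTION"
CONSTANT_PSTH = "CONSTANT_PSTH"
CCHALF_NONPOSITIVE = "CCHALF_NONPOSITIVE"
ALL_ZERO_PSTH = "ALL_ZERO_PSTH"

# Warning flags on defined values
NEGATIVE_SPE = "NEGATIVE_SPE"
CCNORM_EXCEEDS_ONE = "CCNORM_EXCEEDS_ONE"
CCNORM_IMPLAUSIBLE = "CCNORM_IMPLAUSIBLE"
NP_NEGATIVE = "NP_NEGATIVE"
SPLITS_DROPPED = "SPLITS_DROPPED"


@dataclass(frozen=True)
class MetricValue:
    """A possibly-undefined scalar score with diagnostic flags.

    Attributes
    ----------
    value
        The score, or ``None`` when the metric is undefined on this input.
    flags
        Diagnostic codes. An undefined value always carries at least one
        flag explaining why; a defined value may carry warning flags.
    detail
        Auxiliary quantities (e.g. the raw numerator of an undefined
        ratio) useful for diagnosis.
    """

    value: Optional[float]
    flags: Tuple[str, ...] = ()
    detail: Mapping[str, Any] = field(default_factory=dict)

    @property
    def is_defined(self) -> bool:
        return self.value is not None

    def __float__(self) -> float:
        if self.value is None:
            raise ValueError(f"metric undefined (flags: {', '.join(self.flags)})")
        return float(self.value)

    def __repr__(self) -> str:  # compact: flags only when present
        if self.value is None:
            return f"MetricValue(undefined, flags={list(self.flags)})"
        if self.flags:
            return f"MetricValue({self.value:.6g}, flags={list(self.flags)})"
        return f"MetricValue({self.value:.6g})"


def defined(value: float, *flags: str, **detail: Any) -> MetricValue:
    return MetricValue(float(value), tuple(flags), dict(detail))


def undefined(*flags: str, **detail: Any) -> MetricValue:
    return MetricValue(None, tuple(flags), dict(detail))
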