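"""Internal-ssDNA counting model for S1-END-seq strand counts.

S1 nuclease converts every internal single-stranded region of the telomeric
tract into a two-ended double-strand break. Under the end-counting model each
chromosome end contributes exactly one C-readable end (the natural 5'
terminus) and each internal cut contributes one C-readable and one G-readable
end, so with ``n`` cuts per end the expected C-strand fraction of telomeric
reads is

    f = (n + 1) / (2 n + 1).

Inverting, ``n_raw = (1 - f) / (2 f - 1)``, reported as the ceiling
``n_min`` — a *minimum*, because capture losses can only hide G-ends. A
fraction at or below 0.5 violates the one-ended assumption (the model has no
finite solution) and raises. The fraction also classifies ALT status:
ALT-positive lines sit in 0.4-0.58, ALT-negative lines in 0.98-0.99.

``SsdnaBreakModel``/``SsdnaResults`` wrap the point estimates with binomial
uncertainty on ``f`` (Wilson interval) propagated through the inversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Tuple, Union

from .classifier import StrandCounts

__all__ = [
    "AltCall",
    "SsdnaEstimate",
    "StrandBalanceError",
    "c_strand_fraction",
    "min_ssdna_regions",
    "classify_alt_status",
    "SsdnaBreakModel",
    "SsdnaResults",
]

#: ALT-positive ceiling and ALT-negative floor for the C-strand fraction,
#: taken from the observed ranges (0.4-0.58 vs 0.98-0.99).
DEFAULT_ALT_POSITIVE_MAX = 0.58
DEFAULT_ALT_NEGATIVE_MIN = 0.98

# absolute slack when taking the ceiling of the model inversion, so that
# float noise on an exactly model-generated f = (n+1)/(2n+1) cannot push the
# integer solution up by one
_CEIL_GUARD = 1e-9


class AltCall(str, Enum):
    ALT_POSITIVE = "ALT_positive"
    ALT_NEGATIVE = "ALT_negative"
    INDETERMINATE = "indeterminate"


class StrandBalanceError(ValueError):
    """C-strand fraction <= 0.5: the one-ended-terminus assumption is broken."""


@dataclass(frozen=True)
class SsdnaEstimate:
    """C-strand fraction with the inverted minimum ssDNA-region count."""

    f: float
    n_raw: float
    n_min: int
    alt_call: AltCall

    def to_dict(self) -> dict:
        return {
            "f": self.f,
            "n_raw": self.n_raw,
            "n_min": self.n_min,
            "alt_call": self.alt_call.value,
        }


def c_strand_fraction(counts: Union[StrandCounts, Tuple[int, int]]) -> float:
    """C-strand fraction ``c / (c + g)`` of telomeric reads.

    Ambiguous and non-telomeric reads are excluded from the denominator.
    """
    if isinstance(counts, StrandCounts):
        c, g = counts.c_rich, counts.g_rich
    else:
        c, g = counts
    if c < 0 or g < 0:
        raise ValueError("negative strand counts")
    if c + g == 0:
        raise ValueError("no telomeric reads: C-strand fraction undefined")
    return c / (c + g)


def classify_alt_status(
    f: float,
    alt_positive_max: float = DEFAULT_ALT_POSITIVE_MAX,
    alt_negative_min: float = DEFAULT_ALT_NEGATIVE_MIN,
) -> AltCall:
    """Call ALT status from the C-strand fraction of an S1-END-seq library."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"C-strand fraction must be in [0, 1], got {f}")
    if f <= alt_positive_max:
        return AltCall.ALT_POSITIVE
    if f >= alt_negative_min:
        return AltCall.ALT_NEGATIVE
    return AltCall.INDETERMINATE


def min_ssdna_regions(
    f: float,
    alt_positive_max: float = DEFAULT_ALT_POSITIVE_MAX,
    alt_negative_min: float = DEFAULT_ALT_NEGATIVE_MIN,
) -> SsdnaEstimate:
    """Invert the end-counting model into a minimum ssDNA-region count.

    Valid for ``f`` in (0.5, 1]; ``f = 1`` gives ``n_min = 0`` (no cuts).

    Raises
    ------
    StrandBalanceError
        For ``f <= 0.5`` — the cut count is infinite or undefined, signalling
        that the one-ended assumption does not hold for the library.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"C-strand fraction must be in [0, 1], got {f}")
    if f <= 0.5:
        raise StrandBalanceError(
            f"C-strand fraction {f} <= 0.5 has no finite cut count under the "
            "one-ended end-counting model"
        )
    n_raw = (1.0 - f) / (2.0 * f - 1.0)
    n_min = max(0, math.ceil(n_raw - _CEIL_GUARD))
    return SsdnaEstimate(
        f=f,
        n_raw=n_raw,
        n_min=n_min,
        alt_call=classify_alt_status(f, alt_positive_max, alt_negative_min),
    )


def _wilson_interval(c: int, n: int, z: float = 1.959963984540054) -> Tuple[float, float]:
    # Wilson score interval for a binomial proportion (95% by default)
    phat = c / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


class SsdnaBreakModel:
    """End-counting model of internal ssDNA cuts, built from strand counts.

    Parameters
    ----------
    c_rich, g_rich : int
        Telomeric read counts by strand (ambiguous reads excluded).
    alt_positive_max, alt_negative_min : float
        Classification thresholds on the C-strand fraction.
    """

    def __init__(
        self,
        c_rich: int,
        g_rich: int,
        alt_positive_max: float = DEFAULT_ALT_POSITIVE_MAX,
        alt_negative_min: float = DEFAULT_ALT_NEGATIVE_MIN,
    ) -> None:
        if c_rich < 0 or g_rich < 0:
            raise ValueError("negative strand counts")
        if c_rich + g_rich == 0:
            raise ValueError("no telomeric reads: model undefined")
        self.c_rich = int(c_rich)
        self.g_rich = int(g_rich)
        self.alt_positive_max = alt_positive_max
        self.alt_negative_min = alt_negative_min

    @classmethod
    def from_counts(cls, counts: StrandCounts, **kwargs) -> "SsdnaBreakModel":
        return cls(counts.c_rich, counts.g_rich, **kwargs)

    @property
    def nobs(self) -> int:
        return self.c_rich + self.g_rich

    def fit(self) -> "SsdnaResults":
        """Estimate ``f`` with a Wilson 95% CI and invert the model.

        When the point estimate (or the CI's lower edge) is <= 0.5 the
        corresponding cut count is reported as ``None`` rather than raising:
        at the model level an out-of-range fraction is a diagnostic, not a
        programming error.
        """
        f = c_strand_fraction((self.c_rich, self.g_rich))
        ci = _wilson_interval(self.c_rich, self.nobs)
        se = math.sqrt(f * (1 - f) / self.nobs) if self.nobs > 0 else float("nan")

        def invert(x: float) -> Optional[int]:
            if x <= 0.5:
                return None
            return max(0, math.ceil((1.0 - x) / (2.0 * x - 1.0) - _CEIL_GUARD))

        n_min = invert(f)
        n_raw = (1.0 - f) / (2.0 * f - 1.0) if f > 0.5 else None
        # higher f means fewer cuts: the CI's upper f bounds n from below
        n_ci = (invert(ci[1]), invert(ci[0]))
        return SsdnaResults(
            model=self,
            f=f,
            se_f=se,
            conf_int_f=ci,
            n_raw=n_raw,
            n_min=n_min,
            conf_int_n=n_ci,
            alt_call=classify_alt_status(
                f, self.alt_positive_max, self.alt_negative_min
            ),
        )


@dataclass
class SsdnaResults:
    """Fitted C-strand fraction and minimum internal ssDNA regions per end."""

    model: SsdnaBreakModel
    f: float
    se_f: float
    conf_int_f: Tuple[float, float]
    n_raw: Optional[float]
    n_min: Optional[int]
    conf_int_n: Tuple[Optional[int], Optional[int]]
    alt_call: AltCall

    def to_dict(self) -> dict:
        return {
            "c_rich": self.model.c_rich,
            "g_rich": self.model.g_rich,
            "f": self.f,
            "se_f": self.se_f,
            "conf_int_f": list(self.conf_int_f),
            "n_raw": self.n_raw,
            "n_min": self.n_min,
            "conf_int_n": list(self.conf_int_n),
            "alt_call": self.alt_call.value,
            "thresholds": {
                "alt_positive_max": self.model.alt_positive_max,
                "alt_negative_min": self.model.alt_negative_min,
            },
            "assumptions": "equal capture efficiency of C- and G-readable ends",
        }

    def summary(self) -> str:
        fmt_n = lambda v: "inf (f<=0.5)" if v is None else str(v)
        lines = [
            "Internal ssDNA end-counting model",
            "=" * 46,
            f"{'telomeric reads (C / G)':30s}{self.model.c_rich:>8d} /{self.model.g_rich:>7d}",
            f"{'C-strand fraction f':30s}{self.f:>16.4f}",
            f"{'SE(f)':30s}{self.se_f:>16.4f}",
            f"{'Wilson 95% CI for f':30s}"
            f"{'[%.4f, %.4f]' % self.conf_int_f:>16s}",
            f"{'model solution n_raw':30s}"
            f"{('%16.3f' % self.n_raw) if self.n_raw is not None else 'inf (f<=0.5)':>16s}",
            f"{'min ssDNA regions per end':30s}{fmt_n(self.n_min):>16s}",
            f"{'95% CI for n_min':30s}"
            f"{'[%s, %s]' % (fmt_n(self.conf_int_n[0]), fmt_n(self.conf_int_n[1])):>16s}",
            f"{'ALT call':30s}{self.alt_call.value:>16s}",
        ]
        return "\n".join(lines)
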