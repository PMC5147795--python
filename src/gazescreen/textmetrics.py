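"""Lexical variation metrics of a stimulus text.

Three classical Swedish readability statistics computed from the number of
distinct word types and the total number of word tokens in a text:

* TTR  (type-token ratio)      ``n_type / n_token``
* OVIX (word variation index)  ``log(n_token) / log(2 - log(n_type)/log(n_token))``
* OVR  (word variation ratio)  ``log(n_type) / log(n_token)``

All logarithms are natural.  OVIX is undefined when every token is a
distinct type (``n_type == n_token``), because the denominator becomes
``log(1) = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["TextVariationMetrics", "DegenerateTextError", "text_variation_metrics"]


class DegenerateTextError(ValueError):
    """Raised when a metric is undefined for the given type/token counts."""


@dataclass(frozen=True)
class TextVariationMetrics:
    """Lexical variation summary of a text.

    Attributes
    ----------
    n_type : int
        Number of distinct word types.
    n_token : int
        Total number of word tokens.
    ttr : float
        Type-token ratio, in (0, 1].
    ovix : float
        Word variation index (dimensionless).
    ovr : float
        Word variation ratio, ``<= 1`` whenever ``n_type <= n_token``.
    """

    n_type: int
    n_token: int
    ttr: float
    ovix: float
    ovr: float


def text_variation_metrics(n_type: int, n_token: int) -> TextVariationMetrics:
    """Compute TTR, OVIX and OVR from type and token counts.

    Parameters
    ----------
    n_type, n_token : int
        Distinct-type and total-token counts; requires
        ``1 <= n_type <= n_token`` and ``n_token >= 2``.

    Raises
    ------
    DegenerateTextError
        If ``n_type == n_token`` (OVIX denominator is ``log(1) = 0``).
    ValueError
        For counts outside the valid range.
    """
    n_type = int(n_type)
    n_token = int(n_token)
    if n_token < 2:
        raise ValueError(f"n_token must be >= 2, got {n_token}")
    if not 1 <= n_type <= n_token:
        raise ValueError(
            f"need 1 <= n_type <= n_token, got n_type={n_type}, n_token={n_token}"
        )
    if n_type == n_token:
        raise DegenerateTextError(
            "OVIX is undefined when n_type == n_token "
            "(denominator log(2 - 1) = 0)"
        )

    log_token = math.log(n_token)
    log_type = math.log(n_type)
    ratio = log_type / log_token  # this is OVR; < 1 here since n_type < n_token
    ovix = log_token / math.log(2.0 - ratio)
    return TextVariationMetrics(
        n_type=n_type,
        n_token=n_token,
        ttr=n_type / n_token,
        ovix=ovix,
        ovr=ratio,
    )
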