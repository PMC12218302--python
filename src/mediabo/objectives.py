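"""Scalar modelling targets from raw culture measurements.

Three targets cover the campaigns this package was built around: the mean of
replicate viability readings (basal-media blending), secreted-protein titer
normalised by culture density (yeast carbon-source optimisation), and an
aggregated homeostasis score that rewards both survival and a balanced
lymphocyte subpopulation profile (cytokine optimisation).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

__all__ = ["replicate_target", "specific_productivity", "homeostasis_target"]


def replicate_target(replicates: Sequence[float]) -> float:
    """Arithmetic mean of replicate readings — the modelling target."""
    v = np.asarray(list(replicates), dtype=float)
    if v.size == 0:
        raise ValueError("need at least one replicate")
    if not np.all(np.isfinite(v)):
        raise ValueError("replicates must be finite")
    return float(np.mean(v))


def specific_productivity(titer: float, od600: float) -> float:
    """Relative titer normalised by cell density, in mg/L/OD600."""
    if od600 <= 0:
        raise ValueError("OD600 must be positive")
    return float(titer) / float(od600)


def homeostasis_target(viability: float, fractions: Mapping[str, float]) -> float:
    """Viability factor times the summed NK/T/B subpopulation fractions.

    The viability factor is V when the viability ratio V ≤ 1 and 1/V when
    V > 1, so both cell loss and uncontrolled expansion are penalised and
    the factor is maximal exactly at V = 1.  Inputs are ratios of post- to
    pre-culture quantities.
    """
    v = float(viability)
    if v <= 0:
        raise ValueError("viability ratio must be positive")
    if any(f < 0 for f in fractions.values()):
        raise ValueError("fractions must be nonnegative")
    factor = v if v <= 1.0 else 1.0 / v
    return factor * float(sum(fractions.values()))
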