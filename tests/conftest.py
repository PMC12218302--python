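import numpy as np
import pytest

from mediabo.design_space import DesignFactor, DesignSpace, LinearEqualityConstraint

CO_FEED_TYPES = (
    "Ethanol", "Glycerol", "Sorbitol", "Xylitol", "Mannitol", "Glucose",
    "Fructose", "Galactose", "Mannose", "Trehalose", "Lactose", "Ribose",
    "Sucrose", "Rhamnose", "D-Arabinose", "Xylose", "Citrate", "Pyruvate",
    "Succinate",
)


@pytest.fixture
def yeast_space() -> DesignSpace:
    """Carbon-source optimisation space: glycerol/methanol percentages,
    co-feed type (19 categories) and co-feed concentration."""
    return DesignSpace([
        DesignFactor(name="Glycerol", kind="continuous", lower=0.0, upper=10.0,
                     units="%", phase="Outgrowth"),
        DesignFactor(name="Methanol", kind="continuous", lower=0.0, upper=10.0,
                     units="%", phase="Production"),
        DesignFactor(name="CoFeedType", kind="categorical", categories=CO_FEED_TYPES,
                     phase="Production"),
        DesignFactor(name="CoFeedConc", kind="continuous", lower=0.0, upper=50.0,
                     units="g/L", phase="Production", linked_to="CoFeedType"),
    ])


@pytest.fixture
def blend_space() -> DesignSpace:
    """Four-medium blend whose ratios must sum to one."""
    media = ("DMEM", "AR5", "XVIVO", "RPMI")
    factors = [
        DesignFactor(name=m, kind="continuous", lower=0.0, upper=1.0) for m in media
    ]
    return DesignSpace(factors, [LinearEqualityConstraint({m: 1.0 for m in media}, 1.0)])


@pytest.fixture
def tiny_mixed_space() -> DesignSpace:
    return DesignSpace([
        DesignFactor(name="a", kind="continuous", lower=0.0, upper=1.0),
        DesignFactor(name="b", kind="continuous", lower=0.0, upper=2.0),
        DesignFactor(name="kind", kind="categorical", categories=("p", "q", "r")),
    ])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
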