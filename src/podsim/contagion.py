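"""Agent-level belief-update rules.

Three families of contagion are implemented, all returning an adoption
probability that a single Bernoulli trial then realizes:

* **simple** — a flat, disease-style chance ``p`` per exposure, independent
  of what either agent believes;
* **proportional** — deterministic adoption when the fraction of an agent's
  neighbors already holding the candidate belief reaches a threshold
  ``ratio_alpha`` (complex contagion / peer pressure);
* **cognitive** — adoption probability is a function beta of the distance
  between the agent's current belief and the incoming one.  Three beta shapes
  are provided: inverse-linear, hard threshold, and sigmoid.  The "stubborn"
  sigmoid (steepness 4, shift 2) is the *defensive cognitive contagion* (DCC)
  rule: near beliefs are adopted readily (exposure), distant beliefs are
  almost surely rejected (dissonance).

Updates are discrete jumps: a successful trial sets the holder's belief to
the incoming level, with positive and negative moves treated symmetrically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import BeliefSpace

COGNITIVE_VARIANTS = ("linear", "threshold", "sigmoid")
VARIANTS = ("simple", "proportional") + COGNITIVE_VARIANTS

REFERENCE_MAX_DISTANCE = 6  # the 7-level scale the default parameters target


@dataclass(frozen=True)
class ContagionSpec:
    """Selects the update rule and houses its parameters.

    Only the fields relevant to ``variant`` matter: ``p`` (simple),
    ``ratio_alpha`` (proportional), ``lin_gamma``/``lin_alpha`` (inverse
    linear), ``thr_gamma`` (threshold), ``sig_alpha``/``sig_gamma``
    (sigmoid steepness and shift).  Defaults are the values used in the
    reference experiments (p=0.15, alpha=0.35, DCC sigmoid 4/2).
    """

    variant: str = "sigmoid"
    p: float = 0.15
    ratio_alpha: float = 0.35
    lin_gamma: float = 1.0
    lin_alpha: float = 1.0
    thr_gamma: float = 1.0
    sig_alpha: float = 4.0
    sig_gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown contagion variant {self.variant!r}; choose from {VARIANTS}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"simple-contagion p must be in [0,1], got {self.p}")
        if not 0.0 <= self.ratio_alpha <= 1.0:
            raise ValueError(f"proportional ratio_alpha must be in [0,1], got {self.ratio_alpha}")
        if self.variant == "linear" and self.lin_gamma <= 0:
            # alpha*distance can be 0 (equal beliefs), so the bias alone must
            # keep the denominator positive
            raise ValueError("inverse-linear rule requires lin_gamma > 0")
        if self.thr_gamma < 0 or self.lin_alpha < 0:
            raise ValueError("distance coefficients must be nonnegative")


#: Named parameterizations discussed in the experiments.  "dcc" is the
#: stubborn sigmoid used throughout the cascade comparisons.
PRESETS = {
    "simple": ContagionSpec(variant="simple", p=0.15),
    "proportional": ContagionSpec(variant="proportional", ratio_alpha=0.35),
    "dcc": ContagionSpec(variant="sigmoid", sig_alpha=4.0, sig_gamma=2.0),
    "sigmoid-stubborn": ContagionSpec(variant="sigmoid", sig_alpha=4.0, sig_gamma=2.0),
    "sigmoid-normal": ContagionSpec(variant="sigmoid", sig_alpha=2.0, sig_gamma=3.0),
    "sigmoid-gullible": ContagionSpec(variant="sigmoid", sig_alpha=1.0, sig_gamma=7.0),
    "linear-gullible": ContagionSpec(variant="linear", lin_gamma=1.0, lin_alpha=0.0),
    "linear-normal": ContagionSpec(variant="linear", lin_gamma=1.0, lin_alpha=1.0),
    "linear-stubborn": ContagionSpec(variant="linear", lin_gamma=10.0, lin_alpha=20.0),
    "threshold-gullible": ContagionSpec(variant="threshold", thr_gamma=6.0),
    "threshold-normal": ContagionSpec(variant="threshold", thr_gamma=3.0),
    "threshold-stubborn": ContagionSpec(variant="threshold", thr_gamma=1.0),
}


def preset(name: str) -> ContagionSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown contagion preset {name!r}; choose from {sorted(PRESETS)}") from None


def _require(spec: ContagionSpec, variant: str) -> None:
    if spec.variant != variant:
        raise ValueError(f"operation requires variant={variant!r}, spec has {spec.variant!r}")


def simple_adoption_probability(spec: ContagionSpec) -> float:
    """Flat exposure probability; beliefs play no role."""
    _require(spec, "simple")
    return float(spec.p)


def proportional_adoption(spec: ContagionSpec, neighbor_beliefs, candidate: int) -> float:
    """1 if the fraction of neighbors holding ``candidate`` meets the threshold.

    An agent with no neighbors cannot meet a ratio over an empty set, so the
    result is 0 (isolated agents cannot be peer-pressured).
    """
    _require(spec, "proportional")
    nb = np.asarray(neighbor_beliefs)
    if nb.size == 0:
        return 0.0
    frac = float(np.mean(nb == candidate))
    return 1.0 if frac >= spec.ratio_alpha else 0.0


def linear_beta(spec: ContagionSpec, holder, incoming):
    """Inverse-linear dissonance: 1/(gamma + alpha*distance), clamped to [0,1].

    The raw form can exceed 1 for gamma < 1; since the output is a
    probability it is clamped.
    """
    _require(spec, "linear")
    d = np.abs(np.asarray(holder, dtype=float) - np.asarray(incoming, dtype=float))
    out = np.minimum(1.0, 1.0 / (spec.lin_gamma + spec.lin_alpha * d))
    return float(out) if out.ndim == 0 else out


def threshold_beta(spec: ContagionSpec, holder, incoming):
    """Bounded-confidence step: adopt iff the belief distance is <= gamma."""
    _require(spec, "threshold")
    d = np.abs(np.asarray(holder, dtype=float) - np.asarray(incoming, dtype=float))
    out = (d <= spec.thr_gamma).astype(float)
    return float(out) if out.ndim == 0 else out


def sigmoid_beta(spec: ContagionSpec, holder, incoming):
    """Logistic dissonance/exposure curve: 1/(1 + exp(alpha*(distance - gamma))).

    Evaluated through :func:`scipy.special.expit`, so it is overflow-safe for
    arbitrarily large ``alpha * distance``.  At distance == gamma the value is
    exactly 0.5 regardless of steepness.
    """
    _require(spec, "sigmoid")
    d = np.abs(np.asarray(holder, dtype=float) - np.asarray(incoming, dtype=float))
    out = expit(-spec.sig_alpha * (d - spec.sig_gamma))
    return float(out) if out.ndim == 0 else out


_BETA_DISPATCH = {
    "linear": linear_beta,
    "threshold": threshold_beta,
    "sigmoid": sigmoid_beta,
}


def beta_probability(spec: ContagionSpec, holder, incoming):
    """Pairwise adoption probability for any cognitive variant."""
    try:
        fn = _BETA_DISPATCH[spec.variant]
    except KeyError:
        raise ValueError(
            f"variant {spec.variant!r} has no pairwise beta; use a cognitive variant"
        ) from None
    return fn(spec, holder, incoming)


def adoption_probability(
    spec: ContagionSpec, holder: int, incoming: int, neighbor_beliefs=None
) -> float:
    """Adoption probability for any variant (dispatching on ``spec.variant``)."""
    if spec.variant == "simple":
        return simple_adoption_probability(spec)
    if spec.variant == "proportional":
        if neighbor_beliefs is None:
            raise ValueError("proportional variant needs neighbor_beliefs")
        return proportional_adoption(spec, neighbor_beliefs, incoming)
    return float(beta_probability(spec, holder, incoming))


def adoption_trial(
    spec: ContagionSpec,
    holder: int,
    incoming: int,
    neighbor_beliefs=None,
    rng: np.random.Generator | None = None,
) -> bool:
    """One Bernoulli draw at the variant's adoption probability.

    ``True`` means the caller should set the holder's belief to ``incoming``
    (a discrete jump, never an average).  The rng is owned by the caller so
    that whole simulations stay reproducible under a single seed.
    """
    if rng is None:
        raise ValueError("adoption_trial requires a caller-owned rng")
    prob = adoption_probability(spec, holder, incoming, neighbor_beliefs)
    if prob >= 1.0:
        return True
    if prob <= 0.0:
        return False
    return bool(rng.random() < prob)


def dcc_probability_matrix(space: BeliefSpace, spec: ContagionSpec) -> np.ndarray:
    """R x R matrix of sigmoid adoption probabilities indexed (holder, incoming).

    Symmetric and constant along diagonals, since the rule depends only on
    |holder - incoming|.
    """
    _require(spec, "sigmoid")
    levels = space.levels
    return sigmoid_beta(spec, levels[:, None], levels[None, :])


def dcc_matrix_frame(space: BeliefSpace, spec: ContagionSpec) -> pd.DataFrame:
    """The probability matrix with belief levels as index and columns (CSV-ready)."""
    m = dcc_probability_matrix(space, spec)
    levels = list(space.levels)
    return pd.DataFrame(m, index=levels, columns=levels)


def scale_spec_for_resolution(spec: ContagionSpec, space: BeliefSpace) -> ContagionSpec:
    """Rescale distance-based parameters for a non-default belief resolution.

    The default parameters are calibrated to a 7-level scale (max distance
    6).  On an R-level scale the same *relative* positions are max distance
    R-1 apart, so distance thresholds (``sig_gamma``, ``thr_gamma``) scale by
    (R-1)/6 and per-unit-distance coefficients (``sig_alpha``, ``lin_alpha``)
    by the inverse, keeping the probability profile over relative belief
    distance unchanged.
    """
    factor = space.max_level / REFERENCE_MAX_DISTANCE
    if factor == 1.0:
        return spec
    return replace(
        spec,
        sig_gamma=spec.sig_gamma * factor,
        thr_gamma=spec.thr_gamma * factor,
        sig_alpha=spec.sig_alpha / factor,
        lin_alpha=spec.lin_alpha / factor,
    )
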