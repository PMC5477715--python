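"""Built-in benchmark models.

Each factory returns a :class:`~pmjp.model.PMJPModel` together with its
conventional initial state.  Default kinetic parameters are chosen so that
simulated populations stay in the small-count regime where discrete
stochastic dynamics matter; priors default to Gamma(1, 1) and both are
configurable.
"""

from __future__ import annotations

import numpy as np

from .model import KineticLaw, PMJPModel, Reaction

__all__ = [
    "lotka_volterra",
    "sir_finite",
    "sir_open",
    "birth_death",
    "toggle_switch",
    "fixtures",
]


def _priors(n, priors):
    if priors is None:
        return [(1.0, 1.0)] * n
    return priors


def lotka_volterra(theta=(0.12, 0.6, 0.6, 0.12), priors=None):
    """Predator-prey system; state (X, Y) = (predators, prey).

    X + Y -> 2X + Y   at theta_1 X Y   (predator reproduction)
    X     -> 0        at theta_2 X     (predator death)
    Y     -> 2Y       at theta_3 Y     (prey birth)
    X + Y -> X        at theta_4 X Y   (prey death by predation)

    Default initial state: 7 predators, 20 prey.
    """
    reactions = [
        Reaction("predator_birth", (1, 0), KineticLaw(mass_action=(1, 1))),
        Reaction("predator_death", (-1, 0), KineticLaw(mass_action=(1, 0))),
        Reaction("prey_birth", (0, 1), KineticLaw(mass_action=(0, 1))),
        Reaction("prey_death", (0, -1), KineticLaw(mass_action=(1, 1))),
    ]
    model = PMJPModel(["X", "Y"], reactions, theta, _priors(4, priors))
    return model, np.array([7, 20])


def sir_finite(theta=(0.1, 0.5), priors=None):
    """Closed SIR epidemic; state (S, I, R), constant total population.

    S + I -> 2I  at theta_1 S I
    I     -> R   at theta_2 I

    Default initial state: (10, 5, 0).
    """
    reactions = [
        Reaction("infection", (-1, 1, 0), KineticLaw(mass_action=(1, 1, 0))),
        Reaction("recovery", (0, -1, 1), KineticLaw(mass_action=(0, 1, 0))),
    ]
    model = PMJPModel(["S", "I", "R"], reactions, theta, _priors(2, priors))
    return model, np.array([10, 5, 0])


def sir_open(theta=(0.1, 0.5, 1.0), priors=None):
    """Open SIR: as :func:`sir_finite` plus arrivals 0 -> S at rate theta_3.

    The arrival channel makes the state space unbounded.
    """
    reactions = [
        Reaction("infection", (-1, 1, 0), KineticLaw(mass_action=(1, 1, 0))),
        Reaction("recovery", (0, -1, 1), KineticLaw(mass_action=(0, 1, 0))),
        Reaction("arrival", (1, 0, 0), KineticLaw(mass_action=(0, 0, 0))),
    ]
    model = PMJPModel(["S", "I", "R"], reactions, theta, _priors(3, priors))
    return model, np.array([10, 5, 0])


def birth_death(theta=(150.0, 1.0), priors=None):
    """Single-species immigration-death process; state (X,).

    0 -> X  at theta_1     (constant birth, default 150)
    X -> 0  at theta_2 X   (unit per-capita death)

    Stationary law is Poisson(theta_1/theta_2).  Default initial state 10.
    """
    reactions = [
        Reaction("birth", (1,), KineticLaw(mass_action=(0,))),
        Reaction("death", (-1,), KineticLaw(mass_action=(1,))),
    ]
    model = PMJPModel(["X"], reactions, theta, _priors(2, priors))
    return model, np.array([10])


def toggle_switch(
    theta=(4.0, 4.0, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
    r=0.02,
    priors=None,
):
    """Genetic toggle switch: two mutually repressing genes.

    State (G1, G2, P1, P2) with binary gene activity and discrete protein
    levels.  Eight reactions:

    production:   G1_on -> G1_on + P1  at theta_1;  likewise P2 at theta_2
    degradation:  P1 -> 0 at theta_3 P1;  P2 -> 0 at theta_4 P2
    activation:   G_off -> G_on at theta_5 (gene 1), theta_6 (gene 2)
    deactivation: G1_on -> G1_off at theta_7 exp(r P2);
                  G2_on -> G2_off at theta_8 exp(r P1)

    ``r`` is a known constant controlling repression strength.
    """
    reactions = [
        Reaction("p1_production", (0, 0, 1, 0), KineticLaw(indicators=[(0, 1)])),
        Reaction("p2_production", (0, 0, 0, 1), KineticLaw(indicators=[(1, 1)])),
        Reaction("p1_degradation", (0, 0, -1, 0), KineticLaw(mass_action=(0, 0, 1, 0))),
        Reaction("p2_degradation", (0, 0, 0, -1), KineticLaw(mass_action=(0, 0, 0, 1))),
        Reaction("g1_activation", (1, 0, 0, 0), KineticLaw(indicators=[(0, 0)])),
        Reaction("g2_activation", (0, 1, 0, 0), KineticLaw(indicators=[(1, 0)])),
        Reaction(
            "g1_deactivation", (-1, 0, 0, 0),
            KineticLaw(indicators=[(0, 1)], exponentials=[(3, r)]),
        ),
        Reaction(
            "g2_deactivation", (0, -1, 0, 0),
            KineticLaw(indicators=[(1, 1)], exponentials=[(2, r)]),
        ),
    ]
    model = PMJPModel(["G1", "G2", "P1", "P2"], reactions, theta, _priors(8, priors))
    return model, np.array([1, 0, 0, 0])


def fixtures() -> dict:
    """All benchmark systems as {name: (model, initial_state)}."""
    return {
        "lotka_volterra": lotka_volterra(),
        "sir_finite": sir_finite(),
        "sir_open": sir_open(),
        "birth_death": birth_death(),
        "toggle_switch": toggle_switch(),
    }
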