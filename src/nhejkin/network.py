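"""Reaction networks for complexity-dependent NHEJ repair of DNA double-strand breaks.

Ionising radiation produces simple DSBs (clean ends, repaired by Ku and the
XRCC4/Ligase IV complex, "XL") and complex DSBs (chemically dirty ends that
additionally require DNA-PKcs/Artemis for end processing).  Repair is modelled
as a mass-action reaction network in one of four variants:

``SF1``
    Synapsis formation before end processing.  Protein-bound ends pair in a
    second-order self-reaction; the paired complex ends are then processed.
``SF2``
    End processing before synapsis formation: complex ends are processed
    individually (``C1 -> C1p``) and the processed ends then pair.
``SF3``
    Synapsis formation and end processing merged into a single second-order
    step with rate ``k_EPL`` (ATM-sensitive: ``k_EPL_i`` under inhibition).
``BF``
    Break filling.  The break is a single unit filled by sequentially
    recruited proteins; every reaction is first order, so the system is
    linear.

Species are dimensionless number concentrations; every rate constant has
units of 1/min.  Free NHEJ proteins (Ku, DNA-PKcs/Artemis, XL) are abundant
and of constant concentration, so recruitment steps are pseudo-first-order.
ATM inhibition is modelled by swapping the DNA-PK release rate ``k_pD`` for
``k_pD_i`` (and ``k_EPL``/``k_EP`` for their inhibited members in SF3/BF).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "VARIANTS",
    "ParameterSet",
    "DoseSchedule",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "dose_indicator",
    "evaluate_fluxes",
    "species_for",
    "required_parameters",
    "default_free_parameters",
]

VARIANTS = ("SF1", "SF2", "SF3", "BF")

#: species lists per variant.  RS / RC are bookkeeping pools of repaired
#: simple / complex material enabling conservation checks; they receive mass
#: but never feed back into the dynamics.
_SPECIES = {
    "SF1": ["S0", "S1", "S2", "S3", "C0", "C1", "C2", "C3", "C4", "C5", "RS", "RC"],
    "SF2": ["S0", "S1", "S2", "S3", "C0", "C1", "C1p", "C3", "C4", "C5", "RS", "RC"],
    "SF3": ["S0", "S1", "S2", "S3", "C0", "C1", "C3", "C4", "C5", "RS", "RC"],
    "BF": ["S0", "SKu", "S2", "S3", "C0", "CKu", "C2", "C3", "C4", "C5", "RS", "RC"],
}

_REQUIRED = {
    "SF1": ["b_S", "b_C", "k_a1", "k_LK", "k_LD", "k_d1", "k_d2", "k_EP", "k_pD"],
    "SF2": ["b_S", "b_C", "k_a1", "k_LK", "k_LD", "k_d1", "k_d2", "k_EP", "k_pD"],
    "SF3": ["b_S", "b_C", "k_a1", "k_LK", "k_d1", "k_d2", "k_EPL", "k_pD"],
    "BF": ["b_S", "b_C", "k_a1", "k_a2", "k_a3", "k_d1", "k_d2", "k_EP", "k_pD"],
}

_FREE_DEFAULT = {
    "SF1": ["b_S", "b_C", "k_a1", "k_LK", "k_d1", "k_d2", "k_EP", "k_LD", "k_pD", "k_pD_i"],
    "SF2": ["b_S", "b_C", "k_a1", "k_LK", "k_d1", "k_d2", "k_EP", "k_LD", "k_pD", "k_pD_i"],
    "SF3": ["b_S", "b_C", "k_a1", "k_LK", "k_d1", "k_d2", "k_EPL", "k_EPL_i", "k_pD", "k_pD_i"],
    "BF": ["b_S", "b_C", "k_a1", "k_a2", "k_a3", "k_d1", "k_d2", "k_EP", "k_EP_i", "k_pD", "k_pD_i"],
}

#: control rate -> its ATM-inhibited counterpart, per variant
_INHIBITED_SWAP = {
    "SF1": {"k_pD": "k_pD_i"},
    "SF2": {"k_pD": "k_pD_i"},
    "SF3": {"k_pD": "k_pD_i", "k_EPL": "k_EPL_i"},
    "BF": {"k_pD": "k_pD_i", "k_EP": "k_EP_i"},
}


def species_for(variant: str) -> list[str]:
    """Ordered species list of a model variant."""
    _check_variant(variant)
    return list(_SPECIES[variant])


def required_parameters(variant: str) -> list[str]:
    """Control-condition rate constants the variant's network needs."""
    _check_variant(variant)
    return list(_REQUIRED[variant])


def default_free_parameters(variant: str) -> list[str]:
    """Default free-parameter set used when fitting the variant."""
    _check_variant(variant)
    return list(_FREE_DEFAULT[variant])


def _check_variant(variant: str) -> None:
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; expected one of {VARIANTS}")


@dataclass
class ParameterSet:
    """Named rate constants of the NHEJ repair networks, all in 1/min.

    ``b_S`` / ``b_C`` are production rates of simple / complex DSB *ends*
    during irradiation (one break contributes two ends).  ``k_a1`` is the
    common pseudo-first-order recruitment rate of Ku, DNA-PKcs and XL in the
    SF variants; the BF variant refines it into separate ``k_a1`` (Ku),
    ``k_a2`` (DNA-PKcs) and ``k_a3`` (XL).  ``k_LK`` / ``k_LD`` are synapsis
    formation rates of simple / complex ends, ``k_d1`` / ``k_d2`` the release
    rates of Ku and XL, ``k_EP`` the end-processing rate, ``k_pD`` the
    DNA-PK (Ku + DNA-PKcs) release rate driven by DNA-PKcs phosphorylation,
    and ``k_EPL`` the merged processing+synapsis rate of variant SF3.

    Members suffixed ``_i`` apply under ATM inhibition and default to their
    control counterparts when not given.
    """

    b_S: float | None = None
    b_C: float | None = None
    k_a1: float | None = None
    k_a2: float | None = None
    k_a3: float | None = None
    k_LK: float | None = None
    k_LD: float | None = None
    k_d1: float | None = None
    k_d2: float | None = None
    k_EP: float | None = None
    k_EP_i: float | None = None
    k_pD: float | None = None
    k_pD_i: float | None = None
    k_EPL: float | None = None
    k_EPL_i: float | None = None

    _CONTROL_OF = {"k_pD_i": "k_pD", "k_EPL_i": "k_EPL", "k_EP_i": "k_EP"}

    def value(self, name: str) -> float:
        """Resolved value of ``name``; inhibited members fall back to control."""
        v = getattr(self, name)
        if v is None and name in self._CONTROL_OF:
            v = getattr(self, self._CONTROL_OF[name])
        if v is None:
            raise KeyError(f"parameter {name!r} is not set")
        return float(v)

    def validate(self, variant: str) -> None:
        """Check every rate the variant uses is set and strictly positive.

        The production rates b_S/b_C are sources, not reaction rates, and may
        be zero (a channel without damage input); rate constants must be > 0.
        """
        names = required_parameters(variant) + list(_INHIBITED_SWAP[variant].values())
        for name in names:
            v = self.value(name)
            if name.startswith("b_"):
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"production rate {name!r} must be non-negative, got {v}")
            elif not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name!r} must be strictly positive, got {v}")

    def updated(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)

    def to_dict(self, drop_none: bool = True) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if drop_none:
            d = {k: v for k, v in d.items() if v is not None}
        return {k: float(v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown parameter names: {sorted(bad)}")
        return cls(**{k: float(v) for k, v in d.items()})

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


@dataclass(frozen=True)
class DoseSchedule:
    """Irradiation windows driving DSB-end production.

    The dose-rate indicator u(t) is 1 inside an irradiation window and 0
    outside; windows are right-open ``[T_even, T_odd)`` so that u(T_R) = 0
    for an acute exposure of duration T_R (the Heaviside convention
    H(0) = 0).  ``boundaries`` holds 0 = T0 < T1 < ... < T_{2M-1}; the acute
    schedule is the single window [0, T_R).
    """

    boundaries: tuple[float, ...]

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        if len(b) < 2 or len(b) % 2 != 0:
            raise ValueError("boundaries must contain an even number (>= 2) of times")
        if b[0] < 0 or any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("boundaries must be non-negative and strictly increasing")
        object.__setattr__(self, "boundaries", b)

    @classmethod
    def acute(cls, T_R: float = 0.5) -> "DoseSchedule":
        """Single exposure on [0, T_R); T_R defaults to the 0.5 min laser pulse."""
        return cls((0.0, float(T_R)))

    @classmethod
    def fractionated(cls, boundaries: Sequence[float]) -> "DoseSchedule":
        return cls(tuple(boundaries))

    @property
    def mode(self) -> str:
        return "acute" if len(self.boundaries) == 2 else "fractionated"

    @property
    def T_R(self) -> float:
        """Total time of the exposure pattern (last window edge)."""
        return self.boundaries[-1]

    @property
    def exposure_time(self) -> float:
        """Summed open-window duration (equals T_R for an acute schedule)."""
        b = self.boundaries
        return sum(b[i + 1] - b[i] for i in range(0, len(b), 2))

    def indicator(self, t: float | np.ndarray) -> np.ndarray | int:
        """u(t): 1 inside an irradiation window, 0 outside (right-open)."""
        t = np.asarray(t, dtype=float)
        u = np.zeros(t.shape, dtype=int)
        b = self.boundaries
        for i in range(0, len(b), 2):
            u |= (t >= b[i]) & (t < b[i + 1])
        return u if u.shape else int(u)

    def integrated_exposure(self, t: float) -> float:
        """∫₀ᵗ u(s) ds — open-window time elapsed by t."""
        b, total = self.boundaries, 0.0
        for i in range(0, len(b), 2):
            total += max(0.0, min(t, b[i + 1]) - b[i])
        return total

    def to_dict(self) -> dict:
        if self.mode == "acute":
            return {"mode": "acute", "T_R": self.T_R}
        return {"mode": "fractionated", "boundaries": list(self.boundaries)}

    @classmethod
    def from_dict(cls, d: dict) -> "DoseSchedule":
        if d.get("mode", "acute") == "acute":
            return cls.acute(d.get("T_R", 0.5))
        return cls.fractionated(d["boundaries"])


def dose_indicator(t: float | np.ndarray, sched: DoseSchedule) -> np.ndarray | int:
    """Indicator u(t) of the irradiation window(s); free-function form."""
    return sched.indicator(t)


# reaction order tags
ZERO, FIRST, SECOND_SELF = "zero", "first", "second_self"


@dataclass(frozen=True)
class Reaction:
    """One elementary step: stoichiometry plus a mass-action rate rule.

    ``order`` is ``zero`` (dose-forced production, flux = rate*scale*u(t)),
    ``first`` (flux = rate*[reactant]) or ``second_self`` (X + X -> Y,
    flux = rate*[X]^2, consuming two X per event).  ``param`` is the name of
    the rate constant in :class:`ParameterSet` (already the inhibited member
    for networks built under ATM inhibition); ``scale`` multiplies it (used
    for the ends-vs-breaks bookkeeping of the BF variant).
    """

    name: str
    order: str
    param: str
    reactant: str | None
    products: tuple[tuple[str, int], ...]
    scale: float = 1.0


def _sf_reactions(variant: str) -> list[Reaction]:
    rx = [
        Reaction("simple_production", ZERO, "b_S", None, (("S0", 1),)),
        Reaction("simple_recruitment", FIRST, "k_a1", "S0", (("S1", 1),)),
        Reaction("simple_synapsis", SECOND_SELF, "k_LK", "S1", (("S2", 1),)),
        Reaction("simple_ku_release", FIRST, "k_d1", "S2", (("S3", 1),)),
        Reaction("simple_xl_release", FIRST, "k_d2", "S3", (("RS", 1),)),
        Reaction("complex_production", ZERO, "b_C", None, (("C0", 1),)),
        Reaction("complex_recruitment", FIRST, "k_a1", "C0", (("C1", 1),)),
    ]
    if variant == "SF1":
        rx += [
            Reaction("complex_synapsis", SECOND_SELF, "k_LD", "C1", (("C2", 1),)),
            Reaction("end_processing", FIRST, "k_EP", "C2", (("C3", 1),)),
        ]
    elif variant == "SF2":
        rx += [
            Reaction("end_processing", FIRST, "k_EP", "C1", (("C1p", 1),)),
            Reaction("complex_synapsis", SECOND_SELF, "k_LD", "C1p", (("C3", 1),)),
        ]
    else:  # SF3: merged synapsis + processing
        rx += [
            Reaction("synapsis_processing", SECOND_SELF, "k_EPL", "C1", (("C3", 1),)),
        ]
    rx += [
        Reaction("xl_recruitment", FIRST, "k_a1", "C3", (("C4", 1),)),
        Reaction("dnapk_release", FIRST, "k_pD", "C4", (("C5", 1),)),
        Reaction("complex_xl_release", FIRST, "k_d2", "C5", (("RC", 1),)),
    ]
    return rx


def _bf_reactions(breaks_mode: str) -> list[Reaction]:
    # BF species are whole breaks; with b_S/b_C counting ends (default) the
    # zero-order production is halved so one break absorbs two produced ends.
    s = 0.5 if breaks_mode == "ends" else 1.0
    return [
        Reaction("simple_production", ZERO, "b_S", None, (("S0", 1),), scale=s),
        Reaction("simple_ku_binding", FIRST, "k_a1", "S0", (("SKu", 1),)),
        Reaction("simple_xl_binding", FIRST, "k_a3", "SKu", (("S2", 1),)),
        Reaction("simple_ku_release", FIRST, "k_d1", "S2", (("S3", 1),)),
        Reaction("simple_xl_release", FIRST, "k_d2", "S3", (("RS", 1),)),
        Reaction("complex_production", ZERO, "b_C", None, (("C0", 1),), scale=s),
        Reaction("complex_ku_binding", FIRST, "k_a1", "C0", (("CKu", 1),)),
        Reaction("dnapkcs_binding", FIRST, "k_a2", "CKu", (("C2", 1),)),
        Reaction("end_processing", FIRST, "k_EP", "C2", (("C3", 1),)),
        Reaction("xl_binding", FIRST, "k_a3", "C3", (("C4", 1),)),
        Reaction("dnapk_release", FIRST, "k_pD", "C4", (("C5", 1),)),
        Reaction("complex_xl_release", FIRST, "k_d2", "C5", (("RC", 1),)),
    ]


class ReactionNetwork:
    """A model variant's reaction system dX/dt = SM @ R(X, p, t).

    ``SM`` is the stoichiometric matrix (species x reactions); column j holds
    the net change of every species per firing of reaction j (a second-order
    self-reaction consumes 2 of its reactant and produces 1 complex).
    ``R(X, p, t)`` is the mass-action flux vector with zero-order fluxes
    gated by the dose indicator u(t).
    """

    def __init__(
        self,
        variant: str,
        params: ParameterSet,
        schedule: DoseSchedule | None = None,
        condition: str = "control",
        breaks_mode: str = "ends",
    ):
        _check_variant(variant)
        if condition not in ("control", "inhibited"):
            raise ValueError(f"unknown condition {condition!r}")
        if breaks_mode not in ("ends", "breaks"):
            raise ValueError(f"unknown breaks_mode {breaks_mode!r}")
        params.validate(variant)

        self.variant = variant
        self.condition = condition
        self.breaks_mode = breaks_mode
        self.params = params
        self.schedule = schedule or DoseSchedule.acute()
        self.species = _SPECIES[variant]
        self.n_species = len(self.species)
        self._index = {s: i for i, s in enumerate(self.species)}

        base = _bf_reactions(breaks_mode) if variant == "BF" else _sf_reactions(variant)
        swap = _INHIBITED_SWAP[variant] if condition == "inhibited" else {}
        self.reactions = [
            replace(r, param=swap.get(r.param, r.param)) for r in base
        ]
        self.n_reactions = len(self.reactions)

        # resolved rate constants, reactant indices and stoichiometric matrix
        self._rates = np.array(
            [params.value(r.param) * r.scale for r in self.reactions]
        )
        self._orders = [r.order for r in self.reactions]
        self._react_idx = np.array(
            [self._index[r.reactant] if r.reactant else -1 for r in self.reactions]
        )
        SM = np.zeros((self.n_species, self.n_reactions))
        for j, r in enumerate(self.reactions):
            if r.reactant is not None:
                SM[self._index[r.reactant], j] -= 2.0 if r.order == SECOND_SELF else 1.0
            for sp, nu in r.products:
                SM[self._index[sp], j] += nu
        self.SM = SM

    # -- flux evaluation ---------------------------------------------------

    def _basis(self, x: np.ndarray, t: float) -> np.ndarray:
        """Per-reaction flux with the rate constant divided out."""
        u = float(self.schedule.indicator(t))
        b = np.empty(self.n_reactions)
        for j, order in enumerate(self._orders):
            if order == ZERO:
                b[j] = u
            elif order == FIRST:
                b[j] = x[self._react_idx[j]]
            else:
                b[j] = x[self._react_idx[j]] ** 2
        return b

    def fluxes(self, x: np.ndarray, t: float) -> np.ndarray:
        """Mass-action flux vector R(X, p, t), ordered as ``self.reactions``."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_species,):
            raise ValueError(
                f"state has {x.shape} entries; {self.variant} has {self.n_species} species"
            )
        if np.any(x < 0):
            bad = self.species[int(np.argmin(x))]
            raise ValueError(f"negative concentration for species {bad!r}")
        return self._rates * self._basis(x, t)

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        """dX/dt = SM @ R; solver-facing (no non-negativity check)."""
        return self.SM @ (self._rates * self._basis(x, t))

    def jacobian(self, t: float, x: np.ndarray) -> np.ndarray:
        """d(rhs)/dX — analytic, used by stiff solvers and the adjoint system."""
        dR = np.zeros((self.n_reactions, self.n_species))
        for j, order in enumerate(self._orders):
            if order == FIRST:
                dR[j, self._react_idx[j]] = self._rates[j]
            elif order == SECOND_SELF:
                dR[j, self._react_idx[j]] = 2.0 * self._rates[j] * x[self._react_idx[j]]
        return self.SM @ dR

    def rhs_param_jacobian(self, t: float, x: np.ndarray, names: Sequence[str]) -> np.ndarray:
        """d(rhs)/dp for the named rate constants (n_species x len(names)).

        Each reaction's flux is linear in its own rate constant, so column p
        is SM @ (basis restricted to reactions governed by p).
        """
        basis = self._basis(np.maximum(x, 0.0), t)
        cols = np.zeros((self.n_species, len(names)))
        for k, nm in enumerate(names):
            sel = np.array([r.param == nm for r in self.reactions])
            if sel.any():
                scaled = np.where(sel, basis * [r.scale for r in self.reactions], 0.0)
                cols[:, k] = self.SM @ scaled
        return cols

    # -- bookkeeping -------------------------------------------------------

    def index(self, species: str) -> int:
        return self._index[species]

    def end_weights(self) -> np.ndarray:
        """Weights turning a state into a total-end (SF) / total-break (BF) count.

        SF variants: single-end species weigh 1, synapses and repaired pools
        weigh 2 (a synapsis joins two ends).  BF: every species is one break.
        """
        if self.variant == "BF":
            return np.ones(self.n_species)
        singles = {"S0", "S1", "C0", "C1", "C1p"}
        return np.array([1.0 if s in singles else 2.0 for s in self.species])

    def produced_total(self, t: float) -> float:
        """∫₀ᵗ (b_S + b_C)·u ds in the network's own counting units."""
        scale = 0.5 if (self.variant == "BF" and self.breaks_mode == "ends") else 1.0
        b = (self.params.value("b_S") + self.params.value("b_C")) * scale
        return b * self.schedule.integrated_exposure(t)

    def __repr__(self) -> str:
        return (
            f"ReactionNetwork({self.variant}, {self.condition}, "
            f"{self.n_species} species, {self.n_reactions} reactions)"
        )


def build_network(
    variant: str,
    params: ParameterSet,
    schedule: DoseSchedule | None = None,
    condition: str = "control",
    breaks_mode: str = "ends",
) -> ReactionNetwork:
    """Construct the reaction network of a model variant.

    Parameters
    ----------
    variant : {"SF1", "SF2", "SF3", "BF"}
        Synapsis-formation variants (second order) or the linear break-filling
        model.
    params : ParameterSet
        Rate constants; every constant the variant uses must be > 0.
    schedule : DoseSchedule, optional
        Irradiation forcing; defaults to an acute 0.5 min exposure.
    condition : {"control", "inhibited"}
        Under ``inhibited`` the ATM-sensitive rates are swapped for their
        ``_i`` members (k_pD always; k_EPL for SF3; k_EP for BF).
    breaks_mode : {"ends", "breaks"}
        Whether b_S/b_C count DSB ends (default; BF production is then
        halved, one break per two ends) or whole breaks.
    """
    return ReactionNetwork(variant, params, schedule, condition, breaks_mode)


def evaluate_fluxes(net: ReactionNetwork, state: np.ndarray, t: float) -> np.ndarray:
    """Flux vector R(X, p, t) of ``net`` at ``state``; rejects negative states."""
    return net.fluxes(state, t)
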