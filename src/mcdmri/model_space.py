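"""Composite tissue models: the taxonomy grammar.

A composite model mixes an intracellular compartment (Stick, Cylinder,
GDRcylinders), an extracellular compartment (Ball, Zeppelin, Tensor) and an
optional isotropically restricted compartment (Dot, Sphere, Astrosticks,
Astrocylinders), sharing one fiber orientation.  Names concatenate
Extra+Intra(+Iso), e.g. ``ZeppelinCylinderDot``.  The full space holds
9 two-compartment and 36 three-compartment models plus the single-tensor
family (Ball, Zeppelin, Tensor) and the Bizeppelin (two co-axial zeppelins,
a 3-D biexponential): 49 models.

Conventions
-----------
* The intracellular restricted (intrinsic) diffusivity and the axial
  diffusivity are one shared symbol ``d_par``; Zeppelin/Tensor extracellular
  compartments share it as their axial eigenvalue.  Sphere, Astrosticks and
  Astrocylinders third compartments also use ``d_par`` as their intrinsic
  diffusivity (parsimony: their radii are the free shape parameters).
* Radial diffusivities are parametrized as ratios of their parent
  eigenvalue, so eigenvalue ordering d_par >= d_perp >= d_perp2 holds by
  construction.
* Volume fractions live on the simplex via stick-breaking; ``f_ec`` is the
  remainder 1 - f_ic - f_iso.
* ``S0`` is a free scale in [0.5, 1.5] for every model, absorbing residual
  b=0 normalization error; it inflates every K equally so rankings are
  unaffected.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from . import compartments as cp
from .protocol import AcquisitionScheme

INTRA = {
    "Stick": ("d_par",),
    "Cylinder": ("d_par", "R"),
    "GDRcylinders": ("d_par", "kappa", "theta_scale"),
}
EXTRA = {
    "Ball": ("d_iso",),
    "Zeppelin": ("d_par", "d_perp"),
    "Tensor": ("d_par", "d_perp", "d_perp2", "alpha_rot"),
}
ISO = {
    "Dot": (),
    "Sphere": ("R_iso",),
    "Astrosticks": (),
    "Astrocylinders": ("R_iso",),
}

#: global parameter order; every model's param_spec follows this order
PARAM_ORDER = (
    "S0",
    "f_ic",
    "f_iso",
    "theta",
    "phi",
    "alpha_rot",
    "d_par",
    "d_par2",
    "d_perp",
    "d_perp2",
    "d_iso",
    "R",
    "kappa",
    "theta_scale",
    "R_iso",
)

# transform kinds: linear (bounded), log (bounded, log scale), angle
# (unconstrained), frac (stick-breaking), ratio:<parent> (fraction of a
# previously transformed symbol)
_DIFF_LO, _DIFF_HI = 1e-11, 1e-8
_R_LO, _R_HI = 1e-7, 2e-5
_BOUND_NUDGE = 1e-8


@dataclass(frozen=True)
class ParamSpec:
    symbol: str
    lo: float
    hi: float
    kind: str  # linear | log | angle | frac | ratio
    parent: str | None = None


_BASE_SPECS = {
    "S0": ParamSpec("S0", 0.5, 1.5, "linear"),
    "f_ic": ParamSpec("f_ic", 0.0, 1.0, "frac"),
    "f_iso": ParamSpec("f_iso", 0.0, 1.0, "frac"),
    "theta": ParamSpec("theta", -np.inf, np.inf, "angle"),
    "phi": ParamSpec("phi", -np.inf, np.inf, "angle"),
    "alpha_rot": ParamSpec("alpha_rot", -np.inf, np.inf, "angle"),
    "d_par": ParamSpec("d_par", _DIFF_LO, _DIFF_HI, "log"),
    "d_par2": ParamSpec("d_par2", _DIFF_LO, _DIFF_HI, "log"),
    "d_perp": ParamSpec("d_perp", 0.0, 1.0, "ratio", "d_par"),
    "d_iso": ParamSpec("d_iso", _DIFF_LO, _DIFF_HI, "log"),
    "R": ParamSpec("R", _R_LO, _R_HI, "log"),
    "kappa": ParamSpec("kappa", 1e-2, 10.0, "log"),
    "theta_scale": ParamSpec("theta_scale", 1e-8, 1e-5, "log"),
    "R_iso": ParamSpec("R_iso", _R_LO, _R_HI, "log"),
}

#: physiological defaults used as the cold fitting start
DEFAULTS = {
    "S0": 1.0,
    "f_ic": 0.35,
    "f_iso": 0.15,
    "theta": np.pi / 2,
    "phi": 0.0,
    "alpha_rot": 0.0,
    "d_par": 1.7e-9,
    "d_par2": 5e-10,
    "d_perp": 7e-10,
    "d_perp2": 5e-10,
    "d_iso": 1.5e-9,
    "R": 2e-6,
    "kappa": 2.0,
    "theta_scale": 1e-6,
    "R_iso": 1e-6,
}


class CompositeModel:
    """A named compartment combination with a flat constrained parameter set."""

    def __init__(self, intra: str | None, extra: str | None, iso: str | None,
                 special: str | None = None) -> None:
        self.intra = intra
        self.extra = extra
        self.iso = iso
        self.special = special
        if special == "Bizeppelin":
            self.name = "Bizeppelin"
        else:
            self.name = (extra or "") + (intra or "") + (iso or "")
        self.param_spec = self._build_spec()
        self.symbols = tuple(p.symbol for p in self.param_spec)

    # -- structure ---------------------------------------------------------------
    @property
    def n_compartments(self) -> int:
        if self.special == "Bizeppelin":
            return 1
        return sum(x is not None for x in (self.intra, self.extra, self.iso))

    @property
    def oriented(self) -> bool:
        return (
            self.intra is not None
            or self.extra in ("Zeppelin", "Tensor")
            or self.special == "Bizeppelin"
        )

    @property
    def K(self) -> int:
        return len(self.param_spec)

    def _build_spec(self) -> tuple[ParamSpec, ...]:
        syms: set[str] = {"S0"}
        if self.special == "Bizeppelin":
            syms |= {"f_ic", "theta", "phi", "d_par", "d_perp", "d_par2", "d_perp2"}
        else:
            if self.intra:
                syms |= set(INTRA[self.intra])
            if self.extra:
                syms |= set(EXTRA[self.extra])
            if self.iso:
                syms |= set(ISO[self.iso])
            n_comp = self.n_compartments
            if n_comp >= 2:
                syms.add("f_ic")
            if n_comp >= 3:
                syms.add("f_iso")
            if self.oriented:
                syms |= {"theta", "phi"}
        specs = []
        for s in PARAM_ORDER:
            if s not in syms:
                continue
            if s == "d_perp2":
                parent = "d_par2" if self.special == "Bizeppelin" else "d_perp"
                specs.append(ParamSpec("d_perp2", 0.0, 1.0, "ratio", parent))
            else:
                specs.append(_BASE_SPECS[s])
        return tuple(specs)

    def default_params(self) -> dict[str, float]:
        p = {s: DEFAULTS[s] for s in self.symbols}
        if "f_ic" in p and "f_iso" not in p and self.special != "Bizeppelin":
            p["f_ic"] = 0.5
        return p

    # -- prediction --------------------------------------------------------------
    def _fractions(self, params: dict[str, float]) -> tuple[float, float, float]:
        f_ic = params.get("f_ic", 0.0) if self.intra else 0.0
        f_iso = params.get("f_iso", 0.0) if self.iso else 0.0
        f_ec = 1.0 - f_ic - f_iso
        if f_ic < -1e-12 or f_iso < -1e-12 or f_ec < -1e-12:
            raise ValueError("volume fractions must be >= 0 and sum to 1")
        return f_ic, f_ec, f_iso

    def predict(self, params: dict[str, float], scheme: AcquisitionScheme) -> np.ndarray:
        """Signal S = S0 [f_ic E_intra + f_ec E_extra + f_iso E_iso] per row."""
        missing = [s for s in self.symbols if s not in params]
        if missing:
            raise ValueError(f"{self.name}: missing parameters {missing}")
        p = params
        S0 = p["S0"]
        if self.special == "Bizeppelin":
            n = cp.orientation_vector(p["theta"], p["phi"])
            f = p["f_ic"]
            if not (0 <= f <= 1):
                raise ValueError("Bizeppelin fraction must be in [0, 1]")
            z1 = cp.zeppelin_signal(scheme, n, p["d_par"], p["d_perp"])
            z2 = cp.zeppelin_signal(scheme, n, p["d_par2"], p["d_perp2"])
            return S0 * (f * z1 + (1 - f) * z2)

        f_ic, f_ec, f_iso = self._fractions(p)
        n = cp.orientation_vector(p["theta"], p["phi"]) if self.oriented else None
        total = np.zeros(len(scheme))
        if self.intra:
            if self.intra == "Stick":
                e = cp.stick_signal(scheme, n, p["d_par"])
            elif self.intra == "Cylinder":
                e = cp.cylinder_signal(scheme, n, p["d_par"], p["d_par"], p["R"])
            else:  # GDRcylinders
                e = cp.gdr_cylinders_signal(
                    scheme, n, p["d_par"], p["d_par"], p["kappa"], p["theta_scale"]
                )
            total = total + f_ic * e
        if self.extra:
            if self.extra == "Ball":
                e = cp.ball_signal(scheme, p["d_iso"])
            elif self.extra == "Zeppelin":
                e = cp.zeppelin_signal(scheme, n, p["d_par"], p["d_perp"])
            else:  # Tensor
                e = cp.tensor_signal(
                    scheme, p["theta"], p["phi"], p["alpha_rot"],
                    p["d_par"], p["d_perp"], p["d_perp2"],
                )
            total = total + f_ec * e
        if self.iso:
            if self.iso == "Dot":
                e = cp.dot_signal(scheme)
            elif self.iso == "Sphere":
                e = cp.sphere_signal(scheme, p["d_par"], p["R_iso"])
            elif self.iso == "Astrosticks":
                e = cp.astrosticks_signal(scheme, p["d_par"])
            else:  # Astrocylinders
                e = cp.astrocylinders_signal(scheme, p["d_par"], p["R_iso"])
            total = total + f_iso * e
        return S0 * total

    def __repr__(self) -> str:
        return f"CompositeModel({self.name}, K={self.K})"


# -- taxonomy enumeration ---------------------------------------------------------


def enumerate_taxonomy() -> list[CompositeModel]:
    """All 49 models: 9 two-compartment, 36 three-compartment, Bizeppelin,
    Tensor, Zeppelin, Ball."""
    models = []
    for ex, ic in product(EXTRA, INTRA):
        models.append(CompositeModel(ic, ex, None))
    for ex, ic, iso in product(EXTRA, INTRA, ISO):
        models.append(CompositeModel(ic, ex, iso))
    models.append(CompositeModel(None, None, None, special="Bizeppelin"))
    models.append(CompositeModel(None, "Tensor", None))
    models.append(CompositeModel(None, "Zeppelin", None))
    models.append(CompositeModel(None, "Ball", None))
    return models


_REGISTRY: dict[str, CompositeModel] | None = None


def get_model(name: str) -> CompositeModel:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = {m.name: m for m in enumerate_taxonomy()}
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}") from None


def taxonomy_group(model: CompositeModel | str) -> str:
    """Ranking group: 'i', 'ii', 'iii' or 'dt'.

    (i) three-compartment, anisotropic extracellular (Zeppelin/Tensor),
    Dot/Sphere third compartment; (ii) same but Astrosticks/Astrocylinders
    third compartment; (iii) everything else except the single full tensor
    ('dt'), which ranks on its own at the bottom.
    """
    m = get_model(model) if isinstance(model, str) else model
    if m.n_compartments == 3 and m.extra in ("Zeppelin", "Tensor"):
        return "i" if m.iso in ("Dot", "Sphere") else "ii"
    if m.name == "Tensor":
        return "dt"
    return "iii"


def parent_model(model: CompositeModel) -> CompositeModel | None:
    """The next-simpler model in the nesting hierarchy (for warm starts).

    Reductions, in order of preference: GDRcylinders -> Cylinder -> Stick;
    Tensor (extra) -> Zeppelin; Sphere -> Dot; Astrocylinders ->
    Astrosticks; drop the third compartment; drop the intracellular
    compartment; Bizeppelin/Tensor -> Zeppelin -> Ball.
    """
    if model.special == "Bizeppelin":
        return get_model("Zeppelin")
    if model.intra == "GDRcylinders":
        return get_model((model.extra or "") + "Cylinder" + (model.iso or ""))
    if model.intra == "Cylinder":
        return get_model((model.extra or "") + "Stick" + (model.iso or ""))
    if model.extra == "Tensor" and (model.intra or model.iso):
        return get_model("Zeppelin" + (model.intra or "") + (model.iso or ""))
    if model.iso == "Sphere":
        return get_model((model.extra or "") + (model.intra or "") + "Dot")
    if model.iso == "Astrocylinders":
        return get_model((model.extra or "") + (model.intra or "") + "Astrosticks")
    if model.iso is not None:
        return get_model((model.extra or "") + (model.intra or ""))
    if model.intra is not None:
        return get_model(model.extra)
    if model.name == "Tensor":
        return get_model("Zeppelin")
    if model.name == "Zeppelin":
        return get_model("Ball")
    return None


def warm_start_order(models: list[CompositeModel]) -> list[CompositeModel]:
    """Order models so every model's parent (when in the list) precedes it."""
    by_k = sorted(models, key=lambda m: (m.K, m.name))
    return by_k


# -- constrained <-> unconstrained reparametrization -------------------------------


def _logit(x: np.ndarray | float) -> np.ndarray | float:
    return np.log(x) - np.log1p(-x)


def _expit(u: np.ndarray | float) -> np.ndarray | float:
    from scipy.special import expit

    return expit(u)


def _clip01(x: float) -> float:
    return float(np.clip(x, _BOUND_NUDGE, 1.0 - _BOUND_NUDGE))


def transform_params(model: CompositeModel, params: dict[str, float]) -> np.ndarray:
    """Map a constrained parameter dict to an unconstrained vector.

    Fractions use stick-breaking logits (f_ic, then f_iso/(1-f_ic)); bounded
    positives use a logit on their log-scale position within bounds; ratio
    symbols use the logit of the ratio to their parent; angles pass through.
    Values on closed bounds are nudged inward by 1e-8 of the range.
    """
    u = []
    for spec in model.param_spec:
        v = params[spec.symbol]
        if spec.kind == "angle":
            u.append(v)
        elif spec.kind == "linear":
            u.append(_logit(_clip01((v - spec.lo) / (spec.hi - spec.lo))))
        elif spec.kind == "log":
            t = (np.log(max(v, 1e-300)) - np.log(spec.lo)) / (np.log(spec.hi) - np.log(spec.lo))
            u.append(_logit(_clip01(t)))
        elif spec.kind == "ratio":
            u.append(_logit(_clip01(v / params[spec.parent])))
        elif spec.kind == "frac":
            if spec.symbol == "f_ic":
                u.append(_logit(_clip01(v)))
            else:  # f_iso stick-breaking on the remainder
                rem = 1.0 - params.get("f_ic", 0.0)
                u.append(_logit(_clip01(v / rem if rem > 0 else 0.5)))
        else:  # pragma: no cover
            raise RuntimeError(f"unknown transform kind {spec.kind}")
    return np.array(u, dtype=float)


def untransform_params(model: CompositeModel, u: np.ndarray) -> dict[str, float]:
    """Inverse of :func:`transform_params` (bijective within open bounds)."""
    if len(u) != model.K:
        raise ValueError(f"{model.name}: expected {model.K} values, got {len(u)}")
    params: dict[str, float] = {}
    for spec, ui in zip(model.param_spec, u):
        if spec.kind == "angle":
            v = float(ui)
        elif spec.kind == "linear":
            v = spec.lo + (spec.hi - spec.lo) * _expit(ui)
        elif spec.kind == "log":
            v = float(np.exp(np.log(spec.lo) + (np.log(spec.hi) - np.log(spec.lo)) * _expit(ui)))
        elif spec.kind == "ratio":
            v = float(params[spec.parent] * _expit(ui))
        else:  # frac
            if spec.symbol == "f_ic":
                v = float(_expit(ui))
            else:
                v = float((1.0 - params.get("f_ic", 0.0)) * _expit(ui))
        params[spec.symbol] = v
    return params


def bound_flags(model: CompositeModel, params: dict[str, float], rel: float = 1e-3) -> dict[str, str]:
    """Symbols whose fitted value sits within ``rel`` (of range, log-range
    for log-scale symbols) of a bound, e.g. kappa pinned at its upper
    bound 10."""
    flags: dict[str, str] = {}
    for spec in model.param_spec:
        v = params[spec.symbol]
        if spec.kind == "linear":
            t = (v - spec.lo) / (spec.hi - spec.lo)
        elif spec.kind == "log":
            t = (np.log(v) - np.log(spec.lo)) / (np.log(spec.hi) - np.log(spec.lo))
        elif spec.kind == "ratio":
            t = v / params[spec.parent]
        elif spec.kind == "frac":
            t = v
        else:
            continue
        if t <= rel:
            flags[spec.symbol] = "lower"
        elif t >= 1.0 - rel:
            flags[spec.symbol] = "upper"
    return flags
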