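"""Generic Mamdani fuzzy-inference engine.

Implements the classical max-min Mamdani pipeline on piecewise-linear
(triangular / trapezoidal) membership functions:

    crisp inputs -> fuzzification -> min-AND rule firing -> min (clipping)
    implication -> max aggregation -> defuzzification (discretized centroid
    or center-average).

The engine is fully generic; the population-pharmacokinetic evaluation
system built on top of it lives in :mod:`fuzzpk.popk`.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

logger = logging.getLogger("fuzzpk")

#: Supported out-of-range policies for fuzzification.
OUT_OF_RANGE_POLICIES = ("saturate_extremes", "clamp_to_universe")
#: Supported defuzzifiers.
DEFUZZIFIERS = ("discretized_centroid", "center_average")

DEFAULT_GRID_RESOLUTION = 10_001


class ConfigurationError(ValueError):
    """Raised when a fuzzy-system configuration is structurally invalid."""


class NoRuleFired(RuntimeError):
    """Raised when every rule fires with strength zero for a given input.

    Callers that evaluate batches of models (the software robot) catch this
    and record a diagnostic row instead of a number; it is never silently
    mapped to a crisp value.
    """


# ---------------------------------------------------------------------------
# Membership functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear fuzzy set on the real line.

    Parameters
    ----------
    shape:
        ``"triangular"`` with breakpoints ``(a, b, c)`` (apex at ``b``) or
        ``"trapezoidal"`` with breakpoints ``(a, b, c, d)`` (plateau on
        ``[b, c]``). Breakpoints must be non-decreasing.
    open_left, open_right:
        Open-shoulder flags: with ``open_left`` the degree saturates at 1
        for every x below the (left) peak breakpoint, with ``open_right``
        for every x above the (right) peak breakpoint. Used to extend the
        extreme terms of a variable beyond its universe.
    """

    shape: str
    params: tuple[float, ...]
    open_left: bool = False
    open_right: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.shape == "triangular":
            if len(self.params) != 3:
                raise ConfigurationError(
                    f"triangular membership function needs 3 breakpoints, got {self.params}")
        elif self.shape == "trapezoidal":
            if len(self.params) != 4:
                raise ConfigurationError(
                    f"trapezoidal membership function needs 4 breakpoints, got {self.params}")
        else:
            raise ConfigurationError(f"unknown membership shape {self.shape!r}")
        if any(q < p for p, q in zip(self.params, self.params[1:])):
            raise ConfigurationError(
                f"membership breakpoints must be non-decreasing, got {self.params}")

    @property
    def _abcd(self) -> tuple[float, float, float, float]:
        """Internal trapezoid form; a triangle (a,b,c) maps to (a,b,b,c)."""
        if self.shape == "triangular":
            a, b, c = self.params
            return a, b, b, c
        return self.params  # type: ignore[return-value]

    @property
    def center(self) -> float:
        """Center used by the center-average defuzzifier.

        Apex for a triangle, plateau midpoint for a trapezoid.
        """
        a, b, c, d = self._abcd
        return 0.5 * (b + c)

    @property
    def support(self) -> tuple[float, float]:
        a, _, _, d = self._abcd
        return a, d

    def __call__(self, x, *, force_open_left: bool = False,
                 force_open_right: bool = False):
        """Degree of membership of ``x`` (scalar or array), in [0, 1]."""
        a, b, c, d = self._abcd
        x = np.asarray(x, dtype=float)
        mu = np.zeros_like(x)
        # rising edge
        if b > a:
            sel = (x > a) & (x < b)
            mu = np.where(sel, (x - a) / (b - a), mu)
        # plateau (apex)
        mu = np.where((x >= b) & (x <= c), 1.0, mu)
        # falling edge
        if d > c:
            sel = (x > c) & (x < d)
            mu = np.where(sel, (d - x) / (d - c), mu)
        if self.open_left or force_open_left:
            mu = np.where(x < b, 1.0, mu)
        if self.open_right or force_open_right:
            mu = np.where(x > c, 1.0, mu)
        return mu if mu.ndim else float(mu)

    def to_dict(self) -> dict:
        return {
            "shape": self.shape,
            "params": list(self.params),
            "open_left": self.open_left,
            "open_right": self.open_right,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MembershipFunction":
        return cls(shape=d["shape"], params=tuple(d["params"]),
                   open_left=bool(d.get("open_left", False)),
                   open_right=bool(d.get("open_right", False)))


def mf_eval(mf: MembershipFunction, x: float) -> float:
    """Evaluate a membership function at a crisp point."""
    if not np.isfinite(x):
        raise ValueError(f"membership evaluation requires a finite input, got {x}")
    return float(mf(x))


# ---------------------------------------------------------------------------
# Linguistic variables
# ---------------------------------------------------------------------------

@dataclass
class LinguisticVariable:
    """Named variable with a universe interval and ordered linguistic terms.

    Term order matters: the first and last terms are the *extreme* terms
    used by the ``saturate_extremes`` out-of-range policy.
    """

    name: str
    universe: tuple[float, float]
    terms: dict[str, MembershipFunction]

    def __post_init__(self) -> None:
        lo, hi = self.universe
        self.universe = (float(lo), float(hi))
        if not self.universe[0] < self.universe[1]:
            raise ConfigurationError(
                f"variable {self.name!r}: universe lower bound must be below upper, "
                f"got {self.universe}")
        if not self.terms:
            raise ConfigurationError(f"variable {self.name!r} declares no terms")

    @property
    def term_names(self) -> list[str]:
        return list(self.terms)

    def fuzzify(self, x: float, policy: str = "saturate_extremes") -> dict[str, float]:
        """Map a crisp value to a degree for every term.

        Out-of-range handling:

        * ``saturate_extremes`` — the first/last term behave as open
          shoulders (degree 1 beyond their peak), so any finite x receives
          a nonzero degree in at least one term.
        * ``clamp_to_universe`` — x is clipped to the universe and the
          membership functions are evaluated exactly as configured.
        """
        if policy not in OUT_OF_RANGE_POLICIES:
            raise ConfigurationError(f"unknown out-of-range policy {policy!r}")
        if not np.isfinite(x):
            raise ValueError(f"variable {self.name!r}: input must be finite, got {x}")
        if policy == "clamp_to_universe":
            x = min(max(x, self.universe[0]), self.universe[1])
        names = self.term_names
        out: dict[str, float] = {}
        for i, name in enumerate(names):
            mf = self.terms[name]
            if policy == "saturate_extremes":
                out[name] = float(mf(x, force_open_left=(i == 0),
                                     force_open_right=(i == len(names) - 1)))
            else:
                out[name] = float(mf(x))
        return out

    def to_dict(self) -> dict:
        return {
            "universe": list(self.universe),
            "terms": {n: mf.to_dict() for n, mf in self.terms.items()},
        }

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "LinguisticVariable":
        return cls(name=name, universe=tuple(d["universe"]),
                   terms={n: MembershipFunction.from_dict(md)
                          for n, md in d["terms"].items()})


def fuzzify(var: LinguisticVariable, x: float,
            policy: str = "saturate_extremes") -> dict[str, float]:
    """Functional form of :meth:`LinguisticVariable.fuzzify`."""
    return var.fuzzify(x, policy)


# ---------------------------------------------------------------------------
# Rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FuzzyRule:
    """IF-AND-THEN rule: one antecedent term per input variable, AND-connected."""

    antecedent: tuple[tuple[str, str], ...]  # ((variable, term), ...)
    consequent: str
    rule_id: int | None = None

    @classmethod
    def make(cls, antecedent: dict[str, str], consequent: str,
             rule_id: int | None = None) -> "FuzzyRule":
        return cls(tuple(antecedent.items()), consequent, rule_id)

    @property
    def antecedent_dict(self) -> dict[str, str]:
        return dict(self.antecedent)

    def to_dict(self) -> dict:
        d = {"if": dict(self.antecedent), "then": self.consequent}
        if self.rule_id is not None:
            d["id"] = self.rule_id
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyRule":
        return cls.make(d["if"], d["then"], d.get("id"))


def rule_strength(rule: FuzzyRule, fuzzified: dict[str, dict[str, float]]) -> float:
    """Firing strength: minimum of the antecedent degrees (AND = min)."""
    degrees = []
    for var, term in rule.antecedent:
        if var not in fuzzified:
            raise ValueError(f"rule references variable {var!r} missing from fuzzified inputs")
        degrees.append(fuzzified[var][term])
    return float(min(degrees))


# ---------------------------------------------------------------------------
# Defuzzifiers
# ---------------------------------------------------------------------------

def defuzz_centroid(aggregated: np.ndarray, grid: np.ndarray) -> float:
    """Discretized center of gravity sum(x*mu)/sum(mu) of an aggregated profile.

    ``aggregated`` is the max-aggregated membership profile sampled on the
    uniform ``grid`` over the output universe. An identically-zero profile
    means no rule fired and raises :class:`NoRuleFired`.
    """
    mu = np.asarray(aggregated, dtype=float)
    s = mu.sum()
    if s <= 0.0:
        raise NoRuleFired("aggregated output profile is identically zero")
    return float(np.dot(grid, mu) / s)


def defuzz_center_average(fired: list[tuple[MembershipFunction, float]],
                          universe: tuple[float, float],
                          grid_resolution: int = DEFAULT_GRID_RESOLUTION) -> float:
    """Center-average defuzzifier: C = sum(b_i * A_i) / sum(A_i).

    ``b_i`` is each fired consequent's center (apex / plateau midpoint) and
    ``A_i`` the area under the consequent clipped at its firing strength,
    integrated over the output universe. One term per *rule*: the same
    consequent fired by several rules contributes once per rule.
    """
    fired = [(mf, s) for mf, s in fired if s > 0.0]
    if not fired:
        raise NoRuleFired("no rule fired with positive strength")
    x = np.linspace(universe[0], universe[1], grid_resolution)
    num = 0.0
    den = 0.0
    for mf, s in fired:
        area = float(np.trapezoid(np.minimum(mf(x), s), x))
        num += mf.center * area
        den += area
    if den <= 0.0:
        raise NoRuleFired("fired consequents have zero total area")
    return num / den


# ---------------------------------------------------------------------------
# The inference system
# ---------------------------------------------------------------------------

@dataclass
class FISOptions:
    """Inference options. AND=min, implication=min (clipping), aggregation=max
    are fixed — the classical Mamdani max-min reading."""

    defuzzifier: str = "discretized_centroid"
    grid_resolution: int = DEFAULT_GRID_RESOLUTION
    out_of_range: str = "saturate_extremes"

    def __post_init__(self) -> None:
        if self.defuzzifier not in DEFUZZIFIERS:
            raise ConfigurationError(f"unknown defuzzifier {self.defuzzifier!r}")
        if self.out_of_range not in OUT_OF_RANGE_POLICIES:
            raise ConfigurationError(f"unknown out-of-range policy {self.out_of_range!r}")
        if not (isinstance(self.grid_resolution, int) and self.grid_resolution >= 2):
            raise ConfigurationError("grid_resolution must be an integer >= 2")

    def to_dict(self) -> dict:
        return {"and": "min", "implication": "min", "aggregation": "max",
                "defuzzifier": self.defuzzifier,
                "grid_resolution": self.grid_resolution,
                "out_of_range": self.out_of_range}

    @classmethod
    def from_dict(cls, d: dict) -> "FISOptions":
        return cls(defuzzifier=d.get("defuzzifier", "discretized_centroid"),
                   grid_resolution=int(d.get("grid_resolution", DEFAULT_GRID_RESOLUTION)),
                   out_of_range=d.get("out_of_range", "saturate_extremes"))


class MamdaniFIS:
    """Mamdani max-min fuzzy inference system with crisp scalar output."""

    def __init__(self, inputs: list[LinguisticVariable], output: LinguisticVariable,
                 rules: list[FuzzyRule], options: FISOptions | None = None):
        self.inputs = list(inputs)
        self.output = output
        self.rules = list(rules)
        self.options = options or FISOptions()
        self._validate()
        self._grid: np.ndarray | None = None
        self._term_profiles: dict[str, np.ndarray] | None = None

    # -- construction -------------------------------------------------------

    def _validate(self) -> None:
        input_names = [v.name for v in self.inputs]
        if len(set(input_names)) != len(input_names):
            raise ConfigurationError("duplicate input variable names")
        terms = {v.name: set(v.term_names) for v in self.inputs}
        out_terms = set(self.output.term_names)
        for rule in self.rules:
            ante = rule.antecedent_dict
            if set(ante) != set(input_names):
                raise ConfigurationError(
                    f"rule {rule.rule_id}: antecedent variables {sorted(ante)} "
                    f"do not match declared inputs {sorted(input_names)}")
            for var, term in ante.items():
                if term not in terms[var]:
                    raise ConfigurationError(
                        f"rule {rule.rule_id}: unknown term {term!r} for variable {var!r}")
            if rule.consequent not in out_terms:
                raise ConfigurationError(
                    f"rule {rule.rule_id}: unknown output term {rule.consequent!r}")

    def _ensure_grid(self) -> None:
        if self._grid is None:
            lo, hi = self.output.universe
            self._grid = np.linspace(lo, hi, self.options.grid_resolution)
            self._term_profiles = {name: mf(self._grid)
                                   for name, mf in self.output.terms.items()}

    # -- inference ----------------------------------------------------------

    def fuzzify_inputs(self, values: dict[str, float]) -> dict[str, dict[str, float]]:
        missing = {v.name for v in self.inputs} - set(values)
        if missing:
            raise ValueError(f"missing input values for {sorted(missing)}")
        return {v.name: v.fuzzify(values[v.name], self.options.out_of_range)
                for v in self.inputs}

    def rule_strengths(self, values: dict[str, float]) -> list[float]:
        fuzzified = self.fuzzify_inputs(values)
        return [rule_strength(r, fuzzified) for r in self.rules]

    def evaluate(self, values: dict[str, float], defuzzifier: str | None = None) -> float:
        """Run the full pipeline on one crisp input vector.

        Raises :class:`NoRuleFired` if every rule has zero strength.
        """
        defuzzifier = defuzzifier or self.options.defuzzifier
        strengths = self.rule_strengths(values)
        if defuzzifier == "center_average":
            fired = [(self.output.terms[r.consequent], s)
                     for r, s in zip(self.rules, strengths) if s > 0.0]
            return defuzz_center_average(fired, self.output.universe,
                                         self.options.grid_resolution)
        # discretized centroid of the max-aggregated profile; rules sharing a
        # consequent reduce to that consequent clipped at their max strength
        self._ensure_grid()
        assert self._grid is not None and self._term_profiles is not None
        level: dict[str, float] = {}
        for rule, s in zip(self.rules, strengths):
            if s > 0.0:
                level[rule.consequent] = max(level.get(rule.consequent, 0.0), s)
        if not level:
            raise NoRuleFired("all rule strengths are zero")
        aggregated = np.zeros_like(self._grid)
        for term, s in level.items():
            np.maximum(aggregated, np.minimum(self._term_profiles[term], s),
                       out=aggregated)
        return defuzz_centroid(aggregated, self._grid)

    def surface(self, var_x: str, var_y: str, fixed: dict[str, float],
                grid: int = 21) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Crisp-output surface over a uniform grid of two free inputs.

        Returns ``(xs, ys, Z)`` where ``Z[i, j] = evaluate({var_x: xs[j],
        var_y: ys[i], **fixed})`` (row-major over y then x).
        """
        names = {v.name: v for v in self.inputs}
        free = {var_x, var_y}
        if var_x not in names or var_y not in names or len(free) != 2:
            raise ValueError("surface needs two distinct declared input variables")
        expected_fixed = set(names) - free
        if set(fixed) != expected_fixed:
            raise ValueError(f"fixed values must cover exactly {sorted(expected_fixed)}")
        xs = np.linspace(*names[var_x].universe, grid)
        ys = np.linspace(*names[var_y].universe, grid)
        Z = np.empty((grid, grid))
        for i, yv in enumerate(ys):
            for j, xv in enumerate(xs):
                Z[i, j] = self.evaluate({var_x: xv, var_y: yv, **fixed})
        return xs, ys, Z

    # -- configuration round-trip -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "inputs": {v.name: v.to_dict() for v in self.inputs},
            "output": {self.output.name: self.output.to_dict()},
            "rules": [r.to_dict() for r in self.rules],
            "options": self.options.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MamdaniFIS":
        inputs = [LinguisticVariable.from_dict(n, vd) for n, vd in d["inputs"].items()]
        (out_name, out_d), = d["output"].items()
        output = LinguisticVariable.from_dict(out_name, out_d)
        rules = [FuzzyRule.from_dict(rd) for rd in d["rules"]]
        return cls(inputs, output, rules, FISOptions.from_dict(d.get("options", {})))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "MamdaniFIS":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        """Stable hash of the full configuration, for run provenance."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_options(self, **changes) -> "MamdaniFIS":
        """Copy of this system with some inference options replaced."""
        return MamdaniFIS(self.inputs, self.output, self.rules,
                          replace(self.options, **changes))
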