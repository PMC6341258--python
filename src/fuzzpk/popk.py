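"""The population-pharmacokinetic model-evaluation fuzzy system.

Concrete Mamdani system whose three inputs are the statistical criteria of
a fitted PopPK model — AIC, SC (Schwarz criterion, labelled CS) and MSE —
and whose crisp output is the Fuzzy System Evaluation (FSE) score on
[0, 100]; lower FSE means a better model.

The published rulebase has three typographical defects (an impossible
"Very" antecedent, a skipped rule, and a duplicated antecedent that leaves
one combination unmapped). They are handled through an explicit
:class:`CorrectionPolicy`: ``corrected`` mode (default) applies the three
registered repairs and yields the exhaustive 5x5x5 = 125-rule base;
``as_printed`` keeps the table verbatim. Every applied correction is
logged at build time.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from importlib import resources

from .fis import (ConfigurationError, FISOptions, FuzzyRule, LinguisticVariable,
                  MamdaniFIS, MembershipFunction)

logger = logging.getLogger("fuzzpk")

TERMS_IN = ("Very Low", "Low", "Medium", "High", "Very High")
TERMS_OUT = ("Optimal", "High Acceptable", "Acceptable", "Low Acceptable", "Rejected")


@dataclass(frozen=True)
class EvaluationInputs:
    """One candidate model's criteria triple (AIC, CS, MSE)."""

    aic: float
    cs: float
    mse: float

    def as_mapping(self) -> dict[str, float]:
        return {"AIC": self.aic, "CS": self.cs, "MSE": self.mse}


# ---------------------------------------------------------------------------
# Input membership parameters. Universes are the hull of each variable's
# membership supports.
# ---------------------------------------------------------------------------

_INPUT_VARIABLES: dict[str, tuple[tuple[float, float], dict[str, tuple[str, tuple]]]] = {
    "AIC": ((670.0, 680.0), {
        "Very Low": ("trapezoidal", (670.0, 670.0, 670.3, 672.5)),
        "Low": ("triangular", (670.0, 672.5, 675.0)),
        "Medium": ("triangular", (672.5, 675.0, 677.5)),
        "High": ("triangular", (675.0, 677.5, 680.0)),
        "Very High": ("trapezoidal", (677.5, 679.7, 680.0, 680.0)),
    }),
    "CS": ((676.6, 698.0), {
        "Very Low": ("trapezoidal", (676.6, 679.6, 680.4, 683.4)),
        "Low": ("triangular", (680.0, 683.8, 687.5)),
        "Medium": ("triangular", (683.8, 687.5, 691.3)),
        "High": ("triangular", (687.5, 691.3, 695.0)),
        "Very High": ("trapezoidal", (691.0, 695.0, 695.0, 698.0)),
    }),
    "MSE": ((0.092, 0.14), {
        "Very Low": ("trapezoidal", (0.092, 0.092, 0.09397, 0.104)),
        "Low": ("triangular", (0.0921, 0.104, 0.116)),
        "Medium": ("triangular", (0.104, 0.116, 0.128)),
        "High": ("triangular", (0.116, 0.128, 0.14)),
        "Very High": ("trapezoidal", (0.128, 0.1384, 0.14, 0.14)),
    }),
}

# Output "Evaluation" variable; the three-parameter High Acceptable term is
# triangular (its shape tag is omitted in the published table).
_OUTPUT_VARIABLE: tuple[tuple[float, float], dict[str, tuple[str, tuple]]] = (
    (0.0, 100.0), {
        "Optimal": ("trapezoidal", (0.0, 0.0, 10.0, 30.0)),
        "High Acceptable": ("triangular", (10.0, 30.0, 50.0)),
        "Acceptable": ("triangular", (30.0, 50.0, 70.0)),
        "Low Acceptable": ("triangular", (50.0, 70.0, 90.0)),
        "Rejected": ("trapezoidal", (70.0, 90.0, 100.0, 100.0)),
    })


# ---------------------------------------------------------------------------
# The rulebase exactly as published. Quirks preserved verbatim:
#   * rule 5's MSE antecedent is printed as the impossible label "Very" with
#     consequent Optimal — read as Very High (as_printed keeps Optimal);
#   * rule 6 (Very Low, Low, Very Low) is skipped entirely;
#   * rule 80 duplicates rule 100's antecedent (High, Very High, Very High),
#     leaving (High, Very Low, Very High) unmapped.
# ---------------------------------------------------------------------------

_O, _HA, _A, _LA, _R = TERMS_OUT
_VL, _L, _M, _H, _VH = TERMS_IN

_PRINTED_RULES: list[tuple[int, str, str, str, str]] = [
    (1, _VL, _VL, _VL, _O), (2, _VL, _VL, _L, _HA), (3, _VL, _VL, _M, _A),
    (4, _VL, _VL, _H, _LA), (5, _VL, _VL, _VH, _O),
    (7, _VL, _L, _L, _HA), (8, _VL, _L, _M, _A), (9, _VL, _L, _H, _LA),
    (10, _VL, _L, _VH, _R),
    (11, _VL, _M, _VL, _HA), (12, _VL, _M, _L, _HA), (13, _VL, _M, _M, _LA),
    (14, _VL, _M, _H, _LA), (15, _VL, _M, _VH, _R),
    (16, _VL, _H, _VL, _A), (17, _VL, _H, _L, _A), (18, _VL, _H, _M, _LA),
    (19, _VL, _H, _H, _R), (20, _VL, _H, _VH, _R),
    (21, _VL, _VH, _VL, _LA), (22, _VL, _VH, _L, _LA), (23, _VL, _VH, _M, _R),
    (24, _VL, _VH, _H, _R), (25, _VL, _VH, _VH, _R),
    (26, _L, _VL, _VL, _O), (27, _L, _VL, _L, _O), (28, _L, _VL, _M, _HA),
    (29, _L, _VL, _H, _LA), (30, _L, _VL, _VH, _R),
    (31, _L, _L, _VL, _O), (32, _L, _L, _L, _HA), (33, _L, _L, _M, _A),
    (34, _L, _L, _H, _LA), (35, _L, _L, _VH, _R),
    (36, _L, _M, _VL, _O), (37, _L, _M, _L, _HA), (38, _L, _M, _M, _A),
    (39, _L, _M, _H, _LA), (40, _L, _M, _VH, _R),
    (41, _L, _H, _VL, _HA), (42, _L, _H, _L, _A), (43, _L, _H, _M, _LA),
    (44, _L, _H, _H, _R), (45, _L, _H, _VH, _R),
    (46, _L, _VH, _VL, _A), (47, _L, _VH, _L, _LA), (48, _L, _VH, _M, _R),
    (49, _L, _VH, _H, _R), (50, _L, _VH, _VH, _R),
    (51, _M, _VL, _VL, _O), (52, _M, _VL, _L, _HA), (53, _M, _VL, _M, _A),
    (54, _M, _VL, _H, _LA), (55, _M, _VL, _VH, _R),
    (56, _M, _L, _VL, _HA), (57, _M, _L, _L, _HA), (58, _M, _L, _M, _A),
    (59, _M, _L, _H, _R), (60, _M, _L, _VH, _R),
    (61, _M, _M, _VL, _A), (62, _M, _M, _L, _A), (63, _M, _M, _M, _LA),
    (64, _M, _M, _H, _R), (65, _M, _M, _VH, _R),
    (66, _M, _H, _VL, _A), (67, _M, _H, _L, _LA), (68, _M, _H, _M, _R),
    (69, _M, _H, _H, _R), (70, _M, _H, _VH, _R),
    (71, _M, _VH, _VL, _LA), (72, _M, _VH, _L, _LA), (73, _M, _VH, _M, _R),
    (74, _M, _VH, _H, _R), (75, _M, _VH, _VH, _R),
    (76, _H, _VL, _VL, _A), (77, _H, _VL, _L, _A), (78, _H, _VL, _M, _LA),
    (79, _H, _VL, _H, _R), (80, _H, _VH, _VH, _R),
    (81, _H, _L, _VL, _LA), (82, _H, _L, _L, _LA), (83, _H, _L, _M, _R),
    (84, _H, _L, _H, _R), (85, _H, _L, _VH, _R),
    (86, _H, _M, _VL, _LA), (87, _H, _M, _L, _LA), (88, _H, _M, _M, _R),
    (89, _H, _M, _H, _R), (90, _H, _M, _VH, _R),
    (91, _H, _H, _VL, _LA), (92, _H, _H, _L, _R), (93, _H, _H, _M, _R),
    (94, _H, _H, _H, _R), (95, _H, _H, _VH, _R),
    (96, _H, _VH, _VL, _LA), (97, _H, _VH, _L, _LA), (98, _H, _VH, _M, _R),
    (99, _H, _VH, _H, _R), (100, _H, _VH, _VH, _R),
    (101, _VH, _VL, _VL, _A), (102, _VH, _VL, _L, _LA), (103, _VH, _VL, _M, _R),
    (104, _VH, _VL, _H, _R), (105, _VH, _VL, _VH, _R),
    (106, _VH, _L, _VL, _LA), (107, _VH, _L, _L, _LA), (108, _VH, _L, _M, _R),
    (109, _VH, _L, _H, _R), (110, _VH, _L, _VH, _R),
    (111, _VH, _M, _VL, _LA), (112, _VH, _M, _L, _LA), (113, _VH, _M, _M, _R),
    (114, _VH, _M, _H, _R), (115, _VH, _M, _VH, _R),
    (116, _VH, _H, _VL, _R), (117, _VH, _H, _L, _R), (118, _VH, _H, _M, _R),
    (119, _VH, _H, _H, _R), (120, _VH, _H, _VH, _R),
    (121, _VH, _VH, _VL, _R), (122, _VH, _VH, _L, _R), (123, _VH, _VH, _M, _R),
    (124, _VH, _VH, _H, _R), (125, _VH, _VH, _VH, _R),
]


@dataclass(frozen=True)
class Correction:
    """One registered repair of the printed rulebase."""

    rule_id: int
    field: str
    printed: str
    corrected: str
    rationale: str


#: The registered corrections applied in ``corrected`` mode.
CORRECTIONS: tuple[Correction, ...] = (
    Correction(5, "consequent", "Optimal", "Rejected",
               "antecedent (Very Low, Very Low, Very High): an Optimal consequent "
               "breaks the ordinal progression of rules 1-4 and contradicts the "
               "Rejected pattern of every other Very High-MSE row"),
    Correction(6, "missing rule", "(absent)",
               "(Very Low, Low, Very Low) -> Optimal",
               "rule 6 is skipped in the printed table; the best-possible "
               "neighbours (rules 1, 26, 31) all map to Optimal"),
    Correction(80, "antecedent", "(High, Very High, Very High)",
               "(High, Very Low, Very High)",
               "printed antecedent duplicates rule 100 and leaves "
               "(High, Very Low, Very High) unmapped; consequent Rejected kept"),
)

#: Rule-mode values accepted by :func:`build_reference_fis`.
RULE_MODES = ("corrected", "as_printed")


def _build_variable(name: str, universe, spec: dict) -> LinguisticVariable:
    terms = {t: MembershipFunction(shape, params) for t, (shape, params) in spec.items()}
    return LinguisticVariable(name, universe, terms)


def reference_rules(mode: str = "corrected") -> list[FuzzyRule]:
    """The published rulebase under the given correction mode."""
    if mode not in RULE_MODES:
        raise ConfigurationError(f"unknown rule mode {mode!r}")
    rules: list[FuzzyRule] = []
    for rid, a, c, m, out in _PRINTED_RULES:
        if mode == "corrected":
            if rid == 5:
                out = _R
            elif rid == 80:
                a, c, m = _H, _VL, _VH
        rules.append(FuzzyRule.make({"AIC": a, "CS": c, "MSE": m}, out, rid))
    if mode == "corrected":
        rules.insert(5, FuzzyRule.make({"AIC": _VL, "CS": _L, "MSE": _VL}, _O, 6))
        for corr in CORRECTIONS:
            logger.info("rulebase correction applied: rule %d %s: %s -> %s (%s)",
                        corr.rule_id, corr.field, corr.printed, corr.corrected,
                        corr.rationale)
    return rules


def build_reference_fis(mode: str = "corrected",
                    defuzzifier: str = "discretized_centroid",
                    out_of_range: str = "saturate_extremes",
                    grid_resolution: int = 10_001) -> MamdaniFIS:
    """Build the published PopPK-evaluation system.

    In ``corrected`` mode the rulebase is checked to be the exhaustive
    5x5x5 Cartesian product of antecedent terms, exactly once each
    (125 rules); a completeness failure is a configuration error.
    """
    inputs = [_build_variable(n, u, s) for n, (u, s) in _INPUT_VARIABLES.items()]
    universe, out_spec = _OUTPUT_VARIABLE
    output = _build_variable("Evaluation", universe, out_spec)
    rules = reference_rules(mode)
    options = FISOptions(defuzzifier=defuzzifier, grid_resolution=grid_resolution,
                         out_of_range=out_of_range)
    fis = MamdaniFIS(inputs, output, rules, options)
    if mode == "corrected":
        combos = {tuple(r.antecedent_dict[v] for v in ("AIC", "CS", "MSE"))
                  for r in rules}
        expected = set(itertools.product(TERMS_IN, TERMS_IN, TERMS_IN))
        if len(rules) != 125 or combos != expected:
            raise ConfigurationError(
                f"corrected rulebase must cover the 5x5x5 antecedent product exactly "
                f"once; got {len(rules)} rules, {len(combos)} distinct antecedents")
    return fis


def default_config_path():
    """Path to the packaged default configuration (corrected rulebase)."""
    return resources.files("fuzzpk").joinpath("data/popk_fis.yaml")


def load_default_fis() -> MamdaniFIS:
    """Load the packaged default system from its shipped YAML config."""
    with resources.as_file(default_config_path()) as p:
        return MamdaniFIS.load(p)


def evaluate_model(fis: MamdaniFIS, inputs: EvaluationInputs,
                   defuzzifier: str | None = None) -> float:
    """FSE score of one candidate model from its criteria triple.

    Propagates :class:`fuzzpk.fis.NoRuleFired`; the robot maps that to a
    diagnostic row rather than a number.
    """
    return fis.evaluate(inputs.as_mapping(), defuzzifier=defuzzifier)
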