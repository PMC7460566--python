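"""Mamdani fuzzy fusion of the binary classifiers' outputs.

The crisp outputs of the SVM, CART and RF classifiers (tumor probabilities in
[0, 1]) are fuzzified against two input terms, Healthy (HL) and Tumor (TM).
Eight rules — one per combination of input terms — map onto four output
terms of the final state FS: Healthy, Probably Healthy, Probably Tumor and
Tumor.  Inference is standard Mamdani: rule activation is the min of the
antecedent memberships, each consequent term is clipped at its activation,
the clipped terms are accumulated pointwise with max, and the crisp FS is the
centroid (mass center) of the accumulated membership function.  The rule base
realises a soft majority vote: the consequent is Tumor when all three inputs
say tumor, Probably Tumor when exactly two do, and mirrored on the healthy
side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .classification import ClassifierMetrics, TrainedModel, confusion, metrics, train_classifier

__all__ = [
    "MembershipFunction",
    "trapezoid",
    "triangle",
    "LinguisticVariable",
    "Rule",
    "RuleBase",
    "FuzzySystem",
    "default_system",
    "majority_rule_base",
    "infer",
    "final_class",
    "fuse_and_score",
    "FuzzyFusionClassifier",
]

INPUT_TERMS = ("HL", "TM")
OUTPUT_TERMS = ("HL", "PHL", "PTM", "TM")


@dataclass(frozen=True)
class MembershipFunction:
    """Piecewise-linear membership: trapezoid(a,b,c,d) or triangle(a,b,c)."""

    shape: str
    points: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = {"trapezoid": 4, "triangle": 3}
        if self.shape not in expected:
            raise ValueError(f"unknown membership shape {self.shape!r}")
        if len(self.points) != expected[self.shape]:
            raise ValueError(
                f"{self.shape} needs {expected[self.shape]} breakpoints"
            )
        pts = self.points
        if any(q < p for p, q in zip(pts, pts[1:])):
            raise ValueError(f"breakpoints must be non-decreasing: {pts}")
        if pts[0] < 0 or pts[-1] > 1:
            raise ValueError(f"breakpoints must lie in [0, 1]: {pts}")

    def __call__(self, x: np.ndarray | float) -> np.ndarray | float:
        scalar = np.isscalar(x)
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            warnings.warn("membership input outside [0, 1]; clamping")
            x = np.clip(x, 0.0, 1.0)
        if self.shape == "trapezoid":
            a, b, c, d = self.points
        else:
            a, b, c = self.points
            d = c
            c = b
        mu = np.where((x >= b) & (x <= c), 1.0, np.zeros_like(x))
        if b > a:  # rising edge; a vertical edge (a == b) is the plateau's start
            mu = np.where((x >= a) & (x < b), (x - a) / (b - a), mu)
        if d > c:
            mu = np.where((x > c) & (x <= d), (d - x) / (d - c), mu)
        return float(mu) if scalar else mu


def trapezoid(a: float, b: float, c: float, d: float) -> MembershipFunction:
    return MembershipFunction("trapezoid", (a, b, c, d))


def triangle(a: float, b: float, c: float) -> MembershipFunction:
    return MembershipFunction("triangle", (a, b, c))


@dataclass
class LinguisticVariable:
    """A named variable on [0, 1] with a term -> membership mapping."""

    name: str
    terms: dict[str, MembershipFunction]

    def coverage_ok(self, n_check: int = 201) -> bool:
        """True when every checked point of [0, 1] has positive membership
        in at least one term (term supports must overlap, not merely touch)."""
        xs = np.linspace(0, 1, n_check)
        total = np.zeros_like(xs)
        for mf in self.terms.values():
            total = np.maximum(total, mf(xs))
        return bool(np.all(total > 0))


@dataclass(frozen=True)
class Rule:
    antecedents: tuple[str, ...]  # one input term per input variable
    consequent: str


class RuleBase:
    """A complete rule base: every antecedent combination exactly once."""

    def __init__(self, rules: list[Rule], n_inputs: int = 3):
        combos = [r.antecedents for r in rules]
        if len(set(combos)) != len(combos):
            raise ValueError("duplicate antecedent combination in rule base")
        expected = set(product(INPUT_TERMS, repeat=n_inputs))
        if set(combos) != expected:
            missing = sorted(expected - set(combos))
            raise ValueError(f"rule base incomplete; missing antecedents {missing}")
        for r in rules:
            if r.consequent not in OUTPUT_TERMS:
                raise ValueError(f"unknown consequent term {r.consequent!r}")
        self.rules = list(rules)
        self.n_inputs = n_inputs

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


def majority_rule_base(n_inputs: int = 3) -> RuleBase:
    """The soft-majority rule base over ``n_inputs`` classifier outputs.

    Consequent: TM when every input is TM, HL when every input is HL, PTM
    when a strict majority is TM, PHL when a strict majority is HL.  For an
    even input count an exact tie maps to PTM (consistent with the tumor-
    conservative decision threshold).
    """
    rules = []
    for combo in product(INPUT_TERMS, repeat=n_inputs):
        n_t = combo.count("TM")
        if n_t == n_inputs:
            cons = "TM"
        elif n_t == 0:
            cons = "HL"
        elif n_t * 2 > n_inputs:
            cons = "PTM"
        elif n_t * 2 < n_inputs:
            cons = "PHL"
        else:
            cons = "PTM"
        rules.append(Rule(antecedents=combo, consequent=cons))
    return RuleBase(rules, n_inputs=n_inputs)


@dataclass
class FuzzySystem:
    """Input variables, the output variable and the rule base."""

    inputs: list[LinguisticVariable]
    output: LinguisticVariable
    rules: RuleBase
    grid_n: int = 1001

    def __post_init__(self) -> None:
        if self.grid_n < 101:
            raise ValueError("defuzzification grid must have >= 101 points")
        if len(self.inputs) != self.rules.n_inputs:
            raise ValueError("rule base arity must match the input count")
        for var in [*self.inputs, self.output]:
            if not var.coverage_ok():
                raise ValueError(
                    f"variable {var.name!r} leaves part of [0, 1] uncovered"
                )

    # -- serialisation -----------------------------------------------------
    def to_yaml(self) -> str:
        def var_dict(var: LinguisticVariable) -> dict:
            return {
                "name": var.name,
                "terms": {
                    t: {"shape": mf.shape, "points": list(mf.points)}
                    for t, mf in var.terms.items()
                },
            }

        doc = {
            "inputs": [var_dict(v) for v in self.inputs],
            "output": var_dict(self.output),
            "rules": [
                {"if": list(r.antecedents), "then": r.consequent}
                for r in self.rules
            ],
            "grid_n": self.grid_n,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FuzzySystem":
        doc = yaml.safe_load(text)

        def parse_var(d: dict) -> LinguisticVariable:
            return LinguisticVariable(
                name=d["name"],
                terms={
                    t: MembershipFunction(spec["shape"], tuple(spec["points"]))
                    for t, spec in d["terms"].items()
                },
            )

        inputs = [parse_var(d) for d in doc["inputs"]]
        rules = RuleBase(
            [Rule(tuple(r["if"]), r["then"]) for r in doc["rules"]],
            n_inputs=len(inputs),
        )
        return cls(
            inputs=inputs,
            output=parse_var(doc["output"]),
            rules=rules,
            grid_n=int(doc.get("grid_n", 1001)),
        )


def default_system(n_inputs: int = 3, grid_n: int = 1001) -> FuzzySystem:
    """The default three-classifier fusion system.

    Input terms: HL = trapezoid(0, 0, 0.2, 0.55), TM = trapezoid(0.45, 0.8,
    1, 1); the ramps overlap on [0.45, 0.55] so every crisp input activates
    at least one term (exactly abutting supports would leave the midpoint
    with zero membership and a dead spot in the inference surface).
    Output terms: HL = trapezoid(0, 0, 0.15, 0.35), PHL = triangle(0.25, 0.4,
    0.55), PTM = triangle(0.45, 0.6, 0.75), TM = trapezoid(0.65, 0.85, 1, 1).
    """
    names = ["x_svm", "x_cart", "x_rf", "x_glm"][:n_inputs]
    inputs = [
        LinguisticVariable(
            name=name,
            terms={
                "HL": trapezoid(0.0, 0.0, 0.2, 0.55),
                "TM": trapezoid(0.45, 0.8, 1.0, 1.0),
            },
        )
        for name in names
    ]
    output = LinguisticVariable(
        name="FS",
        terms={
            "HL": trapezoid(0.0, 0.0, 0.15, 0.35),
            "PHL": triangle(0.25, 0.4, 0.55),
            "PTM": triangle(0.45, 0.6, 0.75),
            "TM": trapezoid(0.65, 0.85, 1.0, 1.0),
        },
    )
    return FuzzySystem(
        inputs=inputs,
        output=output,
        rules=majority_rule_base(n_inputs),
        grid_n=grid_n,
    )


def infer(system: FuzzySystem, *crisp_inputs: float) -> float:
    """Run one Mamdani inference and return the defuzzified FS value."""
    if len(crisp_inputs) != len(system.inputs):
        raise ValueError(
            f"expected {len(system.inputs)} inputs, got {len(crisp_inputs)}"
        )
    xs = np.linspace(0.0, 1.0, system.grid_n)
    term_grids = {t: mf(xs) for t, mf in system.output.terms.items()}
    # clipping level per output term = max activation among its rules
    levels = dict.fromkeys(system.output.terms, 0.0)
    for rule in system.rules:
        act = min(
            var.terms[term](x)
            for var, term, x in zip(system.inputs, rule.antecedents, crisp_inputs)
        )
        if act > levels[rule.consequent]:
            levels[rule.consequent] = act
    accumulated = np.zeros_like(xs)
    for term, level in levels.items():
        if level > 0:
            accumulated = np.maximum(accumulated, np.minimum(level, term_grids[term]))
    mass = accumulated.sum()
    if mass == 0.0:
        warnings.warn("no rule fired; returning FS = 0.5")
        return 0.5
    return float((xs * accumulated).sum() / mass)


def final_class(fs: float, threshold: float = 0.5) -> int:
    """Crisp decision: tumor (1) iff FS >= threshold; ties go to tumor."""
    if not 0.0 <= fs <= 1.0:
        raise ValueError(f"FS must lie in [0, 1], got {fs}")
    return int(fs >= threshold)


def fuse_and_score(
    models: list[TrainedModel],
    X_test: np.ndarray,
    y_test: np.ndarray,
    system: FuzzySystem | None = None,
    threshold: float = 0.5,
    use_probabilities: bool = True,
) -> tuple[ClassifierMetrics, np.ndarray, np.ndarray]:
    """Fuse per-sample classifier scores and score the fused decisions.

    Returns ``(metrics, fs_values, predictions)``.  With
    ``use_probabilities=False`` the crisp inputs are the models' hard 0/1
    predictions instead of their tumor probabilities.
    """
    if system is None:
        system = default_system(n_inputs=len(models))
    if len(models) != len(system.inputs):
        raise ValueError("one model per fuzzy input variable required")
    X_test = np.asarray(X_test, dtype=float)
    scores = np.column_stack(
        [
            m.score_samples(X_test) if use_probabilities else m.predict(X_test)
            for m in models
        ]
    ).astype(float)
    fs_values = np.array([infer(system, *row) for row in scores])
    preds = np.array([final_class(fs, threshold) for fs in fs_values])
    return metrics(confusion(y_test, preds)), fs_values, preds


class FuzzyFusionClassifier(ClassifierMixin, BaseEstimator):
    """Fit SVM, CART and RF on the data and fuse them by Mamdani inference.

    Parameters
    ----------
    system : FuzzySystem or None
        Fusion system; the default majority system when None.
    use_probabilities : bool, default=True
        Feed tumor probabilities (True) or hard 0/1 predictions (False) into
        the fuzzy inputs.
    threshold : float, default=0.5
        Decision threshold on the defuzzified FS; ties go to tumor.
    random_state : int, default=0
        Seed fanned out to the three base classifiers.
    """

    def __init__(
        self,
        system: FuzzySystem | None = None,
        use_probabilities: bool = True,
        threshold: float = 0.5,
        random_state: int = 0,
    ):
        self.system = system
        self.use_probabilities = use_probabilities
        self.threshold = threshold
        self.random_state = random_state

    _base_kinds = ("SVM", "CART", "RF")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        self.models_ = [
            train_classifier(kind, X, y, seed=self.random_state)
            for kind in self._base_kinds
        ]
        self.system_ = self.system if self.system is not None else default_system()
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Defuzzified FS value per sample."""
        check_is_fitted(self, "models_")
        X = np.asarray(X, dtype=float)
        crisp = np.column_stack(
            [
                m.score_samples(X) if self.use_probabilities else m.predict(X)
                for m in self.models_
            ]
        ).astype(float)
        return np.array([infer(self.system_, *row) for row in crisp])

    def predict(self, X) -> np.ndarray:
        return np.array(
            [final_class(fs, self.threshold) for fs in self.decision_scores(X)]
        )
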