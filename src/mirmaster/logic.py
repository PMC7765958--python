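"""Multi-valued logical models: regulatory graphs, rules, stable states.

A model is a set of components, each taking discrete levels 0..max_level
(Boolean = 0/1, ternary = 0/1/2), a signed interaction graph, and one
logical rule per non-input component.  Rules are written in a restricted
grammar over threshold literals::

    expression := term (OR term)*
    term       := factor (AND factor)*
    factor     := NOT factor | '(' expression ')' | literal
    literal    := NAME | NAME '>=' INT      (bare NAME means NAME >= 1)

A Boolean rule sets its target to max_level when the expression is true;
multi-valued targets use an ordered list of (level, when) clauses, first
match wins, default 0.  Components without an explicit rule fall back to
the template "max_level iff some activator is at/above its interaction
threshold and no inhibitor is".

The update is synchronous; inputs hold their assigned level and clamped
(perturbed) components ignore their rules.  Stable states are fixed points
of the update map, found by exhaustive enumeration over the free internal
components; output components are pure sinks and are evaluated
functionally, which shrinks the enumeration space.

The packaged hepatic glucose/lipid model (24 components, 37 interactions)
couples insulin and glucagon signaling (Insr-Irs2-Akt, PKA), the
transcriptional layer (Foxo1, ternary Pgc-1a, PPARa/g, Srebp-1c, ChREBP)
and key enzymes (Pck1, G6pc, Gck, Acc, Hsl) to five metabolic outputs:
gluconeogenesis, glycolysis, lipogenesis, lipolysis, adipogenesis.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

HEPATIC_MODEL_RESOURCE = "hepatic_glucose_lipid.json"


# ---------------------------------------------------------------------------
# expression grammar

_TOKEN = re.compile(r"\s*(\(|\)|>=|\d+|[A-Za-z_][A-Za-z0-9_.-]*)")


class _Parser:
    def __init__(self, text: str):
        self.tokens = self._tokenize(text)
        self.pos = 0

    @staticmethod
    def _tokenize(text: str) -> list[str]:
        tokens, i = [], 0
        while i < len(text):
            m = _TOKEN.match(text, i)
            if not m:
                raise ValueError(f"cannot tokenize rule expression at: {text[i:]!r}")
            tokens.append(m.group(1))
            i = m.end()
        return tokens

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of rule expression")
        self.pos += 1
        return tok

    def parse(self):
        node = self.expression()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens in rule expression: {self.tokens[self.pos:]}")
        return node

    def expression(self):
        terms = [self.term()]
        while self.peek() is not None and self.peek().upper() == "OR":
            self.next()
            terms.append(self.term())
        return ("or", terms) if len(terms) > 1 else terms[0]

    def term(self):
        factors = [self.factor()]
        while self.peek() is not None and self.peek().upper() == "AND":
            self.next()
            factors.append(self.factor())
        return ("and", factors) if len(factors) > 1 else factors[0]

    def factor(self):
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of rule expression")
        if tok.upper() == "NOT":
            self.next()
            return ("not", self.factor())
        if tok == "(":
            self.next()
            node = self.expression()
            if self.next() != ")":
                raise ValueError("unbalanced parentheses in rule expression")
            return node
        name = self.next()
        if name in {")", ">=", "("} or name.isdigit():
            raise ValueError(f"unexpected token {name!r} in rule expression")
        threshold = 1
        if self.peek() == ">=":
            self.next()
            lit = self.next()
            if not lit.isdigit():
                raise ValueError("threshold literal must be an integer")
            threshold = int(lit)
        return ("lit", name, threshold)


def parse_expression(text: str):
    """Parse a rule expression into an AST; raises ValueError on bad input."""
    return _Parser(text).parse()


def _eval(node, state: dict[str, int]) -> bool:
    op = node[0]
    if op == "lit":
        return state[node[1]] >= node[2]
    if op == "not":
        return not _eval(node[1], state)
    if op == "and":
        return all(_eval(n, state) for n in node[1])
    return any(_eval(n, state) for n in node[1])


def _literals(node) -> set[str]:
    op = node[0]
    if op == "lit":
        return {node[1]}
    if op == "not":
        return _literals(node[1])
    return set().union(*(_literals(n) for n in node[1]))


def _literal_thresholds(node) -> set[tuple[str, int]]:
    op = node[0]
    if op == "lit":
        return {(node[1], node[2])}
    if op == "not":
        return _literal_thresholds(node[1])
    return set().union(*(_literal_thresholds(n) for n in node[1]))


# ---------------------------------------------------------------------------
# model structure


@dataclass(frozen=True)
class Component:
    name: str
    max_level: int = 1  # 1 = Boolean, 2 = ternary
    role: str = "internal"  # input | internal | output

    def __post_init__(self) -> None:
        if self.max_level not in (1, 2):
            raise ValueError(f"{self.name}: max_level must be 1 or 2")
        if self.role not in ("input", "internal", "output"):
            raise ValueError(f"{self.name}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Interaction:
    source: str
    target: str
    sign: str  # activation | inhibition
    threshold: int = 1  # minimal source level at which the edge is active

    def __post_init__(self) -> None:
        if self.sign not in ("activation", "inhibition"):
            raise ValueError(f"unknown interaction sign {self.sign!r}")


@dataclass
class LogicalRule:
    target: str
    #: ordered (level, expression AST) clauses; first true clause wins, else 0
    clauses: list[tuple[int, object]]


ModelState = dict[str, int]


@dataclass
class LogicalModel:
    components: list[Component]
    interactions: list[Interaction]
    rules: dict[str, LogicalRule] = field(default_factory=dict)
    name: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- structure helpers --------------------------------------------------
    def component(self, name: str) -> Component:
        return self._by_name[name]

    @property
    def inputs(self) -> list[str]:
        return [c.name for c in self.components if c.role == "input"]

    @property
    def outputs(self) -> list[str]:
        return [c.name for c in self.components if c.role == "output"]

    @property
    def internal(self) -> list[str]:
        return [c.name for c in self.components if c.role == "internal"]

    def regulators(self, target: str) -> list[Interaction]:
        return [i for i in self.interactions if i.target == target]

    def validate(self) -> None:
        names = [c.name for c in self.components]
        if len(names) != len(set(names)):
            raise ValueError("duplicate component names")
        self._by_name = {c.name: c for c in self.components}
        for i in self.interactions:
            for end in (i.source, i.target):
                if end not in self._by_name:
                    raise ValueError(f"interaction references undeclared component {end!r}")
            if i.threshold > self._by_name[i.source].max_level or i.threshold < 1:
                raise ValueError(
                    f"interaction {i.source}->{i.target}: threshold {i.threshold} out of range"
                )
            if self._by_name[i.target].role == "input":
                raise ValueError(f"input component {i.target!r} cannot have incoming interactions")
            if self._by_name[i.source].role == "output":
                raise ValueError(f"output component {i.source!r} cannot have outgoing interactions")
        incoming = {c.name: {i.source for i in self.interactions if i.target == c.name}
                    for c in self.components}
        for rule in self.rules.values():
            if rule.target not in self._by_name:
                raise ValueError(f"rule for undeclared component {rule.target!r}")
            if self._by_name[rule.target].role == "input":
                raise ValueError(f"input component {rule.target!r} cannot have a rule")
            target_max = self._by_name[rule.target].max_level
            for level, ast in rule.clauses:
                if not 0 <= level <= target_max:
                    raise ValueError(f"rule for {rule.target!r}: level {level} out of range")
                for name, thr in _literal_thresholds(ast):
                    if name not in incoming[rule.target]:
                        raise ValueError(
                            f"rule for {rule.target!r} references {name!r}, which is not a "
                            "declared regulator"
                        )
                    if thr > self._by_name[name].max_level:
                        raise ValueError(
                            f"rule for {rule.target!r}: literal {name}>={thr} exceeds max level"
                        )

    # -- dynamics -----------------------------------------------------------
    def rule_value(self, target: str, state: ModelState) -> int:
        """The level the target's rule assigns on ``state``."""
        comp = self._by_name[target]
        rule = self.rules.get(target)
        if rule is not None:
            for level, ast in rule.clauses:
                if _eval(ast, state):
                    return level
            return 0
        # default template: active iff >=1 active activator and no active inhibitor
        regs = self.regulators(target)
        if not regs:
            return 0
        activators = [i for i in regs if i.sign == "activation"]
        inhibitors = [i for i in regs if i.sign == "inhibition"]
        active = any(state[i.source] >= i.threshold for i in activators)
        inhibited = any(state[i.source] >= i.threshold for i in inhibitors)
        return comp.max_level if active and not inhibited else 0


@dataclass(frozen=True)
class Perturbation:
    """Clamped component levels: knockout = 0, ectopic = max level."""

    clamps: tuple[tuple[str, int], ...] = ()

    @classmethod
    def knockout(cls, *names: str) -> "Perturbation":
        return cls(tuple((n, 0) for n in names))

    @classmethod
    def from_dict(cls, clamps: dict[str, int]) -> "Perturbation":
        return cls(tuple(sorted(clamps.items())))

    def as_dict(self) -> dict[str, int]:
        return dict(self.clamps)


def update(
    model: LogicalModel, state: ModelState, perturbation: Perturbation | None = None
) -> ModelState:
    """Synchronous image of ``state``: rules applied to every non-clamped,
    non-input component; inputs and clamps are held fixed."""
    clamps = perturbation.as_dict() if perturbation else {}
    for name, level in clamps.items():
        comp = model.component(name)
        if not 0 <= level <= comp.max_level:
            raise ValueError(f"clamp level {level} out of range for {name!r}")
    new: ModelState = {}
    for comp in model.components:
        if comp.name in clamps:
            new[comp.name] = clamps[comp.name]
        elif comp.role == "input":
            new[comp.name] = state[comp.name]
        else:
            new[comp.name] = model.rule_value(comp.name, state)
    return new


def stable_states(
    model: LogicalModel,
    inputs: dict[str, int],
    perturbation: Perturbation | None = None,
    cap: int = 2**24,
) -> list[ModelState]:
    """All fixed points of the synchronous update under the given inputs.

    Enumerates the free internal components exhaustively; outputs (pure
    sinks) are evaluated functionally.  States are returned in lexicographic
    order of component name/level.
    """
    clamps = perturbation.as_dict() if perturbation else {}
    missing = [n for n in model.inputs if n not in inputs and n not in clamps]
    if missing:
        raise ValueError(f"unassigned input components: {missing}")
    for name in list(inputs) + list(clamps):
        if name not in {c.name for c in model.components}:
            raise ValueError(f"unknown component {name!r}")
    base: ModelState = {}
    for name, level in inputs.items():
        comp = model.component(name)
        if not 0 <= level <= comp.max_level:
            raise ValueError(f"input level {level} out of range for {name!r}")
        base[name] = level
    base.update(clamps)

    free = [n for n in sorted(model.internal) if n not in clamps]
    free_outputs = [n for n in sorted(model.outputs) if n not in clamps]
    space = 1
    for n in free:
        space *= model.component(n).max_level + 1
        if space > cap:
            raise ValueError(
                f"free state space exceeds cap ({cap}); clamp components or raise cap"
            )
    ranges = [range(model.component(n).max_level + 1) for n in free]
    found: list[ModelState] = []
    state = dict(base)
    for levels in itertools.product(*ranges):
        state.update(zip(free, levels))
        ok = True
        for n in free:  # early exit on the first unstable component
            if model.rule_value(n, state) != state[n]:
                ok = False
                break
        if not ok:
            continue
        full = dict(state)
        for n in free_outputs:
            full[n] = model.rule_value(n, full)
        found.append({c.name: full[c.name] for c in model.components})
    found.sort(key=lambda s: tuple(s[n] for n in sorted(s)))
    return found


# ---------------------------------------------------------------------------
# environments


@dataclass(frozen=True)
class Environment:
    name: str
    inputs: tuple[tuple[str, int], ...]
    perturbation: Perturbation = Perturbation()

    @classmethod
    def make(
        cls, name: str, inputs: dict[str, int], clamps: dict[str, int] | None = None
    ) -> "Environment":
        return cls(name, tuple(sorted(inputs.items())), Perturbation.from_dict(clamps or {}))


def simulate_environments(
    model: LogicalModel, environments: list[Environment]
) -> pd.DataFrame:
    """Stable-state report: one row per environment (and per stable state if
    several), one column per component."""
    names = sorted(c.name for c in model.components)
    rows, index = [], []
    for env in environments:
        states = stable_states(model, dict(env.inputs), env.perturbation)
        if not states:
            rows.append({n: None for n in names})
            index.append(env.name)
        for k, s in enumerate(states):
            rows.append({n: s[n] for n in names})
            index.append(env.name if len(states) == 1 else f"{env.name}#{k + 1}")
    return pd.DataFrame(rows, index=index, columns=names)


# ---------------------------------------------------------------------------
# serialization


def model_from_dict(data: dict) -> LogicalModel:
    components = [
        Component(c["name"], int(c.get("max_level", 1)), c.get("role", "internal"))
        for c in data.get("components", [])
    ]
    interactions = [
        Interaction(
            i["source"], i["target"], i["sign"], int(i.get("threshold", 1))
        )
        for i in data.get("interactions", [])
    ]
    rules: dict[str, LogicalRule] = {}
    for r in data.get("rules", []):
        target = r["target"]
        if "levels" in r:
            clauses = [
                (int(cl["level"]), parse_expression(cl["when"])) for cl in r["levels"]
            ]
        else:
            comp = next((c for c in components if c.name == target), None)
            top = comp.max_level if comp else 1
            clauses = [(top, parse_expression(r["expression"]))]
        rules[target] = LogicalRule(target=target, clauses=clauses)
    return LogicalModel(
        components=components,
        interactions=interactions,
        rules=rules,
        name=data.get("name", "model"),
    )


def _ast_to_str(node) -> str:
    op = node[0]
    if op == "lit":
        name, thr = node[1], node[2]
        return name if thr == 1 else f"{name}>={thr}"
    if op == "not":
        inner = _ast_to_str(node[1])
        if node[1][0] in ("and", "or"):
            inner = f"({inner})"
        return f"NOT {inner}"
    joiner = " AND " if op == "and" else " OR "
    parts = []
    for n in node[1]:
        s = _ast_to_str(n)
        if op == "and" and n[0] == "or":
            s = f"({s})"
        parts.append(s)
    return joiner.join(parts)


def model_to_dict(model: LogicalModel) -> dict:
    rules = []
    for target in sorted(model.rules):
        rule = model.rules[target]
        max_level = model.component(target).max_level
        if len(rule.clauses) == 1 and rule.clauses[0][0] == max_level:
            rules.append({"target": target, "expression": _ast_to_str(rule.clauses[0][1])})
        else:
            rules.append(
                {
                    "target": target,
                    "levels": [
                        {"level": lv, "when": _ast_to_str(ast)} for lv, ast in rule.clauses
                    ],
                }
            )
    return {
        "name": model.name,
        "components": [
            {"name": c.name, "max_level": c.max_level, "role": c.role}
            for c in model.components
        ],
        "interactions": [
            {"source": i.source, "target": i.target, "sign": i.sign, "threshold": i.threshold}
            for i in model.interactions
        ],
        "rules": rules,
    }


def load_model(path: str | Path) -> LogicalModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def save_model(model: LogicalModel, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=2)
        fh.write("\n")


def to_sbml_qual(model: LogicalModel) -> str:
    """Minimal SBML-qual (Level 3) serialization for interoperability."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
        'xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1" '
        'level="3" version="1" qual:required="true">',
        f'  <model id="{model.name}">',
        "    <qual:listOfQualitativeSpecies>",
    ]
    for c in model.components:
        constant = "true" if c.role == "input" else "false"
        lines.append(
            f'      <qual:qualitativeSpecies qual:id="{c.name}" '
            f'qual:maxLevel="{c.max_level}" qual:constant="{constant}"/>'
        )
    lines.append("    </qual:listOfQualitativeSpecies>")
    lines.append("    <qual:listOfTransitions>")
    for target in sorted({i.target for i in model.interactions}):
        lines.append(f'      <qual:transition qual:id="tr_{target}">')
        lines.append("        <qual:listOfInputs>")
        for i in model.regulators(target):
            effect = "positive" if i.sign == "activation" else "negative"
            lines.append(
                f'          <qual:input qual:qualitativeSpecies="{i.source}" '
                f'qual:thresholdLevel="{i.threshold}" qual:sign="{effect}"/>'
            )
        lines.append("        </qual:listOfInputs>")
        lines.append("        <qual:listOfOutputs>")
        lines.append(
            f'          <qual:output qual:qualitativeSpecies="{target}" '
            'qual:transitionEffect="assignmentLevel"/>'
        )
        lines.append("        </qual:listOfOutputs>")
        lines.append("      </qual:transition>")
    lines.append("    </qual:listOfTransitions>")
    lines.append("  </model>")
    lines.append("</sbml>")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# packaged hepatic model


def hepatic_model(with_mir34a: bool = False) -> LogicalModel:
    """The packaged hepatic glucose/lipid metabolism model.

    ``with_mir34a=True`` adds miR-34a-5p as an optional input inhibiting
    Irs2 (off by default; the 24/37 component/interaction counts refer to
    the base model).
    """
    ref = resources.files("mirmaster").joinpath("models", HEPATIC_MODEL_RESOURCE)
    model = model_from_dict(json.loads(ref.read_text(encoding="utf-8")))
    if with_mir34a:
        components = model.components + [Component("miR34a", 1, "input")]
        interactions = model.interactions + [
            Interaction("miR34a", "Irs2", "inhibition", 1)
        ]
        rules = dict(model.rules)
        rules["Irs2"] = LogicalRule(
            "Irs2", [(1, parse_expression("Insr AND NOT miR34a"))]
        )
        model = LogicalModel(components, interactions, rules, name=model.name + "+miR34a")
    return model


def hepatic_environments() -> list[Environment]:
    """The packaged simulation environments of the hepatic model.

    fed: glucose high; fasting: glucose low, glucagon and circulating fatty
    acids high; plus the three perturbed scenarios (Pgc-1a knockout under
    both regimes, ectopic Irs2 under fasting).
    """
    fed = {"glucose": 1, "glucagon": 0, "FA": 0}
    fasting = {"glucose": 0, "glucagon": 1, "FA": 1}
    return [
        Environment.make("fed", fed),
        Environment.make("fasting", fasting),
        Environment.make("fed_pgc1a_ko", fed, {"Pgc1a": 0}),
        Environment.make("fasting_pgc1a_ko", fasting, {"Pgc1a": 0}),
        Environment.make("fasting_irs2_ectopic", fasting, {"Irs2": 1}),
    ]
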