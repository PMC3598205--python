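"""Config-driven decision-tree engine for rating drug-drug interactions.

The engine interprets a *decision-model configuration* — a rooted graph of
binary (yes/no) clinical questions whose leaves are severity ratings A–E —
and rates a case from its answer set, returning the complete audited
root-to-leaf decision path. The engine is topology-agnostic: the bundled
default model (``epha-dm-v1``, six question sets AIA/SAE/ACT/SUR/ATE/RBR,
13 decision paths, 5 ratings) is just one configuration file.

Two node flavours exist:

* ordinary nodes ask a single question and branch on its answer;
* OR-composite nodes (``any_of``) ask an ordered list of sub-questions and
  take the "yes" branch as soon as one sub-question is answered "yes"
  (short-circuit); only if all sub-questions are "no" is the "no" branch
  taken. The apparent-interaction question set (AIA) is such a composite:
  a single literature report *or* a plausible mechanism suffices to
  progress. A composite counts as one step on a decision path.

AND-coupled question sets (like ATE: a safer alternative exists *and* no
credible dose-adjustment guidelines) need no special node type — they are
chained ordinary nodes whose "no" branches exit to the same rating.

Several nodes may share one *question id* (field ``question``): the model
may need to ask the same clinical question in different contexts with
different downstream consequences (in the default model the whole
ACT→RBR subtree is duplicated so that the SAE answer modulates terminal
severity). An answer set is keyed by question id; any single case visits
at most one node per question.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

RATING_LABELS = ("A", "B", "C", "D", "E")
LEAF_PREFIX = "rating:"


class ConfigError(ValueError):
    """Malformed, cyclic or dangling decision-model configuration."""


class EvaluationError(ValueError):
    """A case could not be rated (e.g. missing answer on the path)."""


def is_leaf(target: str) -> bool:
    return target.startswith(LEAF_PREFIX)


def leaf_rating(target: str) -> str:
    return target[len(LEAF_PREFIX):]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class QuestionNode:
    """A binary question with a yes-branch and a no-branch.

    ``yes_target``/``no_target`` name another node id or a leaf
    (``"rating:X"``). ``question`` is the answer-set key; it defaults to the
    node id. ``any_of`` holds the ordered (sub-question id, text) pairs of
    an OR-composite; it is empty for ordinary nodes.
    """

    id: str
    text: str
    yes_target: str
    no_target: str
    question: str = ""
    any_of: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.question:
            object.__setattr__(self, "question", self.id)

    @property
    def is_composite(self) -> bool:
        return bool(self.any_of)

    @property
    def sub_questions(self) -> tuple[str, ...]:
        """Question ids this node may consume, in asking order."""
        if self.any_of:
            return tuple(q for q, _ in self.any_of)
        return (self.question,)

    def target(self, answer: bool) -> str:
        return self.yes_target if answer else self.no_target


@dataclass(frozen=True)
class DecisionModelConfig:
    name: str
    version: str
    root: str
    nodes: Mapping[str, QuestionNode]
    leaves: frozenset[str]

    @property
    def questions(self) -> tuple[str, ...]:
        """Distinct question ids, in first-appearance (file) order."""
        seen: dict[str, None] = {}
        for node in self.nodes.values():
            for q in node.sub_questions:
                seen.setdefault(q)
        return tuple(seen)


@dataclass(frozen=True)
class AnswerSet:
    """Per-case yes/no answers to the model's questions, possibly partial.

    Only the questions actually visited on the decision path need answers;
    answers to unvisited questions are ignored (with a logged notice).
    """

    case_id: str
    drug_pair: tuple[str, str]
    answers: Mapping[str, bool]

    @staticmethod
    def normalize(raw: Mapping[str, object]) -> dict[str, bool]:
        """Coerce yes/no/true/false/y/n strings and booleans to bool."""
        out: dict[str, bool] = {}
        for key, value in raw.items():
            if isinstance(value, bool):
                out[key] = value
                continue
            token = str(value).strip().lower()
            if token in ("yes", "y", "true", "1"):
                out[key] = True
            elif token in ("no", "n", "false", "0"):
                out[key] = False
            else:
                raise EvaluationError(
                    f"answer to {key!r} must be yes/no, got {value!r}"
                )
        return out


@dataclass(frozen=True)
class DecisionPath:
    """One enumerated root-to-leaf path of a configuration."""

    path_id: int
    steps: tuple[tuple[str, bool], ...]  # (node id, outcome)
    rating: str
    example_answers: Mapping[str, bool]

    def describe(self) -> str:
        body = " ".join(
            f"{nid}={'yes' if ans else 'no'}" for nid, ans in self.steps
        )
        return f"{body} -> {self.rating}" if body else f"-> {self.rating}"


@dataclass(frozen=True)
class DecisionTrace:
    """The audited decision path produced by rating one case.

    ``steps`` records each visited node and its outcome (a composite node
    is one step); ``answers_used`` holds the question-level answers
    actually consumed, so replaying them through the same configuration
    reproduces the trace.
    """

    case_id: str
    drug_pair: tuple[str, str]
    steps: tuple[tuple[str, bool], ...]
    rating: str
    path_id: int
    answers_used: Mapping[str, bool]
    ignored_questions: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# configuration loading


_TOP_KEYS = {"name", "version", "root", "nodes", "leaves"}
_NODE_KEYS = {"text", "yes", "no", "question", "any_of"}


def _normalize_branch_keys(mapping: dict) -> dict:
    # YAML 1.1 resolves bare `yes`/`no` keys to booleans; accept both.
    return {
        {True: "yes", False: "no"}.get(k, k): v for k, v in mapping.items()
    }


def load_config(source: str | Path) -> DecisionModelConfig:
    """Parse and validate a YAML/JSON decision-model document.

    ``source`` may be a filesystem path or the document text itself.
    JSON is a subset of YAML, so both dialects pass through one parser.
    Raises :class:`ConfigError` on parse failure, schema violations,
    dangling targets or cycles.
    """
    text = source.read_text() if isinstance(source, Path) else str(source)
    if isinstance(source, str) and "\n" not in source and Path(source).is_file():
        text = Path(source).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse decision-model document: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("decision-model document must be a mapping")

    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level fields: {sorted(unknown)}")
    missing = {"name", "version", "root", "nodes"} - set(doc)
    if missing:
        raise ConfigError(f"missing required fields: {sorted(missing)}")

    nodes: dict[str, QuestionNode] = {}
    for node_id, raw in dict(doc["nodes"]).items():
        if not isinstance(raw, dict):
            raise ConfigError(f"node {node_id!r}: expected a mapping")
        raw = _normalize_branch_keys(raw)
        unknown = set(raw) - _NODE_KEYS
        if unknown:
            raise ConfigError(f"node {node_id!r}: unknown fields {sorted(unknown)}")
        for branch in ("yes", "no"):
            if branch not in raw:
                raise ConfigError(f"node {node_id!r}: missing {branch!r} target")
        any_of = tuple(
            (str(q), str(t)) for q, t in dict(raw.get("any_of") or {}).items()
        )
        nodes[str(node_id)] = QuestionNode(
            id=str(node_id),
            text=str(raw.get("text", "")),
            yes_target=str(raw["yes"]),
            no_target=str(raw["no"]),
            question=str(raw.get("question", "")),
            any_of=any_of,
        )

    declared = doc.get("leaves")
    if declared is None:
        leaves = frozenset(
            leaf_rating(t)
            for node in nodes.values()
            for t in (node.yes_target, node.no_target)
            if is_leaf(t)
        )
        if is_leaf(str(doc["root"])):
            leaves |= {leaf_rating(str(doc["root"]))}
    else:
        leaves = frozenset(str(r) for r in declared)

    config = DecisionModelConfig(
        name=str(doc["name"]),
        version=str(doc["version"]),
        root=str(doc["root"]),
        nodes=nodes,
        leaves=leaves,
    )
    report = validate_config(config)
    if not report.is_valid:
        raise ConfigError(
            "invalid decision model: " + "; ".join(report.violations)
        )
    return config


def default_config_path() -> Path:
    """Path of the bundled default model (``epha-dm-v1``)."""
    return Path(__file__).parent / "data" / "epha_dm_v1.yaml"


def load_default_config() -> DecisionModelConfig:
    return load_config(default_config_path())


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class ValidationReport:
    """Structural findings for a configuration; empty violations = valid."""

    violations: tuple[str, ...]
    path_count: int | None

    @property
    def is_valid(self) -> bool:
        return not self.violations


def validate_config(config: DecisionModelConfig) -> ValidationReport:
    """Check structural invariants: targets resolve, no cycles, everything
    reachable, leaf ratings legal and all declared ratings attainable.

    Violations are reported in a deterministic order (by check, then by
    node id).
    """
    violations: list[str] = []

    def check_target(owner: str, target: str) -> None:
        if is_leaf(target):
            if leaf_rating(target) not in RATING_LABELS:
                violations.append(
                    f"node {owner!r}: leaf rating {leaf_rating(target)!r} "
                    f"not in {'/'.join(RATING_LABELS)}"
                )
        elif target not in config.nodes:
            violations.append(f"node {owner!r}: dangling target {target!r}")

    check_target("<root>", config.root)
    for node_id in sorted(config.nodes):
        node = config.nodes[node_id]
        check_target(node_id, node.yes_target)
        check_target(node_id, node.no_target)
    if violations:
        return ValidationReport(tuple(violations), None)

    # cycle detection by iterative DFS with colouring
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {nid: WHITE for nid in config.nodes}
    cyclic: list[str] = []
    reachable: set[str] = set()

    def dfs(start: str) -> None:
        stack: list[tuple[str, int]] = [(start, 0)]
        while stack:
            nid, phase = stack.pop()
            if phase == 0:
                if colour[nid] == GREY:
                    cyclic.append(nid)
                    continue
                if colour[nid] == BLACK:
                    continue
                colour[nid] = GREY
                reachable.add(nid)
                stack.append((nid, 1))
                node = config.nodes[nid]
                for target in (node.no_target, node.yes_target):
                    if not is_leaf(target):
                        stack.append((target, 0))
            else:
                colour[nid] = BLACK

    if not is_leaf(config.root):
        dfs(config.root)
    if cyclic:
        violations.append("cycle detected through node(s): " + ", ".join(sorted(set(cyclic))))
        return ValidationReport(tuple(violations), None)

    for nid in sorted(set(config.nodes) - reachable):
        violations.append(f"node {nid!r} unreachable from root")

    reachable_ratings = {
        leaf_rating(t)
        for nid in reachable
        for t in (config.nodes[nid].yes_target, config.nodes[nid].no_target)
        if is_leaf(t)
    }
    if is_leaf(config.root):
        reachable_ratings.add(leaf_rating(config.root))
    for rating in sorted(config.leaves - reachable_ratings):
        violations.append(f"rating {rating} unreachable")
    for rating in sorted(reachable_ratings - config.leaves):
        violations.append(f"rating {rating} reachable but not declared in leaves")

    path_count = None
    if not violations:
        path_count = len(enumerate_paths(config, _validated=True))
    return ValidationReport(tuple(violations), path_count)


# ---------------------------------------------------------------------------
# path enumeration and rating


def enumerate_paths(
    config: DecisionModelConfig, *, _validated: bool = False
) -> list[DecisionPath]:
    """All root-to-leaf paths, depth-first with "yes" explored before "no".

    A composite node contributes a single (node, outcome) step; its
    ``example_answers`` entry answers the first sub-question "yes" for a
    yes-outcome and every sub-question "no" for a no-outcome.
    """
    if not _validated:
        report = validate_config(config)
        if not report.is_valid:
            raise ConfigError(
                "cannot enumerate an invalid model: " + "; ".join(report.violations)
            )

    paths: list[DecisionPath] = []

    def example(node: QuestionNode, answer: bool) -> dict[str, bool]:
        if not node.is_composite:
            return {node.question: answer}
        subs = node.sub_questions
        if answer:
            return {subs[0]: True}
        return {q: False for q in subs}

    def walk(target: str, steps: list[tuple[str, bool]], answers: dict[str, bool]) -> None:
        if is_leaf(target):
            paths.append(
                DecisionPath(
                    path_id=len(paths),
                    steps=tuple(steps),
                    rating=leaf_rating(target),
                    example_answers=dict(answers),
                )
            )
            return
        node = config.nodes[target]
        for answer in (True, False):
            walk(
                node.target(answer),
                steps + [(node.id, answer)],
                {**answers, **example(node, answer)},
            )

    walk(config.root, [], {})
    return paths


def _evaluate_node(node: QuestionNode, answers: Mapping[str, bool]) -> tuple[bool, dict[str, bool]]:
    """Outcome of a node given question-level answers, plus those consumed."""
    if not node.is_composite:
        if node.question not in answers:
            raise EvaluationError(
                f"missing answer for question {node.question!r} "
                f"(node {node.id!r}) on the decision path"
            )
        answer = answers[node.question]
        return answer, {node.question: answer}
    consumed: dict[str, bool] = {}
    for sub in node.sub_questions:  # short-circuit OR
        if sub not in answers:
            raise EvaluationError(
                f"missing answer for sub-question {sub!r} of node {node.id!r} "
                "on the decision path"
            )
        consumed[sub] = answers[sub]
        if answers[sub]:
            return True, consumed
    return False, consumed


def rate_case(config: DecisionModelConfig, answer_set: AnswerSet) -> DecisionTrace:
    """Rate one case, returning its severity and audited decision path.

    Pure function of ``(config, answer_set)``. Answers to questions not
    visited on the path are ignored with a logged notice; a missing answer
    for a visited question raises :class:`EvaluationError` naming it.
    """
    answers = AnswerSet.normalize(answer_set.answers)
    steps: list[tuple[str, bool]] = []
    used: dict[str, bool] = {}
    current = config.root
    for _ in range(len(config.nodes) + 1):
        if is_leaf(current):
            break
        node = config.nodes[current]
        outcome, consumed = _evaluate_node(node, answers)
        steps.append((node.id, outcome))
        used.update(consumed)
        current = node.target(outcome)
    else:  # pragma: no cover - guarded by validate_config
        raise ConfigError("evaluation exceeded node count; cyclic configuration?")

    rating = leaf_rating(current)
    ignored = tuple(sorted(set(answers) - set(used)))
    if ignored:
        logger.info(
            "case %s: ignoring answers to unvisited questions: %s",
            answer_set.case_id, ", ".join(ignored),
        )
    step_key = tuple(steps)
    path_id = next(
        p.path_id for p in enumerate_paths(config, _validated=True)
        if p.steps == step_key
    )
    return DecisionTrace(
        case_id=answer_set.case_id,
        drug_pair=answer_set.drug_pair,
        steps=step_key,
        rating=rating,
        path_id=path_id,
        answers_used=used,
        ignored_questions=ignored,
    )


# ---------------------------------------------------------------------------
# rendering


def _quote(s: str) -> str:
    return '"' + s.replace('"', r'\"') + '"'


def render_paths(
    config: DecisionModelConfig, trace: DecisionTrace | None = None
) -> tuple[str, str]:
    """Return ``(text, dot)`` renderings of the model's decision paths.

    Text: one enumerated path per line. DOT: decision nodes are merged by
    question id (a composite is expanded into its sub-questions, chained
    along the "no" branch), and each enumerated path gets its own terminal
    rating box, so the drawing shows every distinct decision path. When a
    trace is supplied, its nodes and edges are highlighted.
    """
    paths = enumerate_paths(config)
    width = len(str(max(len(paths) - 1, 0)))
    text_lines = [f"[{p.path_id:>{width}}] {p.describe()}" for p in paths]
    text = "\n".join(text_lines) + "\n"

    # question-level node set and merged internal edges
    questions: dict[str, str] = {}  # question id -> text
    edges: dict[tuple[str, str, str], None] = {}  # (src q, label, dst q)

    def entry_question(target: str) -> str:
        node = config.nodes[target]
        return node.sub_questions[0]

    for node in config.nodes.values():
        if node.is_composite:
            for q, t in node.any_of:
                questions.setdefault(q, t)
        else:
            questions.setdefault(node.question, node.text)
        subs = node.sub_questions
        for i, q in enumerate(subs[:-1]):  # composite internal "no" chain
            edges.setdefault((q, "no", subs[i + 1]))
        for q in subs:  # any "yes" exits the node
            if not is_leaf(node.yes_target):
                edges.setdefault((q, "yes", entry_question(node.yes_target)))
        if not is_leaf(node.no_target):
            edges.setdefault((subs[-1], "no", entry_question(node.no_target)))

    # one terminal box per enumerated path
    leaf_edges: list[tuple[str, str, int, str]] = []  # (src q, label, path id, rating)
    for p in paths:
        if not p.steps:
            continue
        node_id, answer = p.steps[-1]
        node = config.nodes[node_id]
        src = node.sub_questions[0] if answer else node.sub_questions[-1]
        leaf_edges.append((src, "yes" if answer else "no", p.path_id, p.rating))

    # trace highlighting: question-level traversal
    hot_nodes: set[str] = set()
    hot_edges: set[tuple[str, str, str]] = set()
    if trace is not None:
        seq: list[tuple[str, bool]] = []  # question-level (q, answer)
        for node_id, _ in trace.steps:
            node = config.nodes[node_id]
            for q in node.sub_questions:
                if q in trace.answers_used:
                    seq.append((q, trace.answers_used[q]))
                    if node.is_composite and trace.answers_used[q]:
                        break
        hot_nodes = {q for q, _ in seq}
        for (q, a), (q2, _) in zip(seq, seq[1:]):
            hot_edges.add((q, "yes" if a else "no", q2))
        if seq:
            q, a = seq[-1]
            hot_edges.add((q, "yes" if a else "no", f"leaf_{trace.path_id}"))

    lines = [f"digraph {_quote(config.name)} {{", "  rankdir=TB;"]
    for q, qtext in questions.items():
        attrs = [f"label={_quote(q)}", "shape=diamond"]
        if qtext:
            attrs.append(f"tooltip={_quote(qtext)}")
        if q in hot_nodes:
            attrs += ["color=red", "penwidth=2"]
        lines.append(f"  {_quote(q)} [{', '.join(attrs)}];")
    if not paths or not paths[0].steps:
        # degenerate model: the root is itself a leaf
        rating = leaf_rating(config.root)
        lines.append(f"  {_quote('leaf_0')} [label={_quote(rating)}, shape=box];")
    for src, label, pid, rating in leaf_edges:
        name = f"leaf_{pid}"
        attrs = [f"label={_quote(rating)}", "shape=box"]
        if trace is not None and pid == trace.path_id:
            attrs += ["style=filled", "fillcolor=mistyrose", "color=red", "penwidth=2"]
        lines.append(f"  {_quote(name)} [{', '.join(attrs)}];")
    for (src, label, dst) in edges:
        attrs = [f"label={_quote(label)}"]
        if (src, label, dst) in hot_edges:
            attrs += ["color=red", "penwidth=2"]
        lines.append(f"  {_quote(src)} -> {_quote(dst)} [{', '.join(attrs)}];")
    for src, label, pid, rating in leaf_edges:
        name = f"leaf_{pid}"
        attrs = [f"label={_quote(label)}"]
        if (src, label, name) in hot_edges:
            attrs += ["color=red", "penwidth=2"]
        lines.append(f"  {_quote(src)} -> {_quote(name)} [{', '.join(attrs)}];")
    lines.append("}")
    return text, "\n".join(lines) + "\n"
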