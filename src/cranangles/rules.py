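"""CN2 rule induction over numeric attributes with a binary class.

Rules are conjunctions of threshold conditions (``attr <= v`` / ``attr > v``)
found by beam search; candidate thresholds are midpoints between
consecutive sorted attribute values whose class composition differs.  Rule
quality is Laplace accuracy ``(correct + 1) / (covered + 2)``.

Two variants are provided:

* **unordered** (default): per-class set covering.  For each class in turn,
  repeatedly find the best rule for that class, remove the positives it
  covers (negatives are kept), and stop when no rule reaches the minimum
  correct coverage or beats the class prior.  Prediction lets all matching
  rules vote, weighted by their correct-coverage counts.
* **ordered**: the classic sequential list — the best rule over either
  class is appended, all examples it covers are removed, and a default
  (majority) rule terminates the list.  Prediction fires the first matching
  rule.

Coverage counts stored on each rule are tallied on the full training set,
so ``correct_count >= min_coverage`` holds for every emitted rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True, order=True)
class Condition:
    attribute: str
    op: str          # "<=" | ">"
    threshold: float

    def matches(self, values: np.ndarray) -> np.ndarray:
        if self.op == "<=":
            return values <= self.threshold
        return values > self.threshold

    def __str__(self) -> str:
        return f"{self.attribute} {self.op} {self.threshold:.2f}"


@dataclass(frozen=True)
class Rule:
    conditions: tuple[Condition, ...]
    predicted_class: str
    coverage: tuple[int, int]  # (correct, incorrect) on the training set

    def matches(self, frame: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(frame), dtype=bool)
        for c in self.conditions:
            vals = frame[c.attribute].to_numpy(dtype=float)
            mask &= np.where(np.isfinite(vals), c.matches(vals), False)
        return mask

    def __str__(self) -> str:
        body = " AND ".join(str(c) for c in self.conditions) or "TRUE"
        return (f"IF {body} THEN sex = {self.predicted_class} "
                f"({self.coverage[0]}, {self.coverage[1]})")


@dataclass
class RuleList:
    rules: list[Rule]
    variant: str              # "unordered" | "ordered"
    default_class: str
    classes: tuple[str, str]
    uncovered_positives: dict[str, int] = field(default_factory=dict)

    def render(self) -> str:
        return "\n".join(str(r) for r in self.rules)


def _candidate_conditions(frame: pd.DataFrame, y: np.ndarray) -> list[Condition]:
    conds: list[Condition] = []
    for attr in frame.columns:
        vals = frame[attr].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        v, lab = vals[ok], y[ok]
        order = np.argsort(v, kind="mergesort")
        v, lab = v[order], lab[order]
        if len(v) < 2:
            continue
        # boundary midpoints: value changes where class composition differs or is mixed
        change = np.nonzero(v[1:] != v[:-1])[0]
        for i in change:
            left = set(lab[v == v[i]].tolist())
            right = set(lab[v == v[i + 1]].tolist())
            if left != right or len(left) > 1:
                thr = (v[i] + v[i + 1]) / 2.0
                conds.append(Condition(attr, "<=", thr))
                conds.append(Condition(attr, ">", thr))
    return conds


def _laplace(correct: int, covered: int) -> float:
    return (correct + 1.0) / (covered + 2.0)


def _find_best_rule(
    frame: pd.DataFrame,
    y: np.ndarray,
    positive: str,
    weights: np.ndarray,
    beam_width: int,
    max_conditions: int,
) -> tuple[tuple[Condition, ...], float] | None:
    """Beam search for the best single rule predicting ``positive``.

    ``weights`` is a 0/1 mask of still-active examples; Laplace quality is
    computed on active examples only.
    """
    conds = _candidate_conditions(frame, y)
    if not conds:
        return None
    pos = (y == positive) & (weights > 0)
    active = weights > 0
    cond_masks = []
    for c in conds:
        vals = frame[c.attribute].to_numpy(dtype=float)
        cond_masks.append(c.matches(vals) & np.isfinite(vals))  # NaN matches nothing

    def quality(mask: np.ndarray) -> tuple[float, int, int]:
        covered = int((mask & active).sum())
        correct = int((mask & pos).sum())
        return _laplace(correct, covered), correct, covered

    empty = np.ones(len(frame), dtype=bool)
    beam: list[tuple[float, tuple[Condition, ...], np.ndarray]] = [
        (quality(empty)[0], (), empty)]
    best: tuple[float, tuple[Condition, ...]] | None = None
    for _depth in range(max_conditions):
        candidates: list[tuple[float, int, tuple[Condition, ...], np.ndarray]] = []
        seen: set[tuple[Condition, ...]] = set()
        for _q, rule_conds, mask in beam:
            used_attrs = {(c.attribute, c.op) for c in rule_conds}
            for ci, cond in enumerate(conds):
                if (cond.attribute, cond.op) in used_attrs:
                    continue
                new_conds = tuple(sorted(rule_conds + (cond,),
                                         key=lambda c: (c.attribute, c.op, c.threshold)))
                if new_conds in seen:
                    continue
                seen.add(new_conds)
                new_mask = mask & cond_masks[ci]
                q, correct, covered = quality(new_mask)
                if covered == 0:
                    continue
                candidates.append((q, correct, new_conds, new_mask))
        if not candidates:
            break
        candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
        beam = [(q, rc, m) for q, _c, rc, m in candidates[:beam_width]]
        top_q, _top_correct, top_conds, _ = candidates[0]
        if best is None or top_q > best[0] + 1e-12:
            best = (top_q, top_conds)
        else:
            break  # no specialization improved the best rule
    if best is None:
        return None
    return best[1], best[0]


def cn2_induce(
    frame: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    beam_width: int = 5,
    min_coverage: int = 15,
    variant: str = "unordered",
    max_conditions: int = 5,
) -> RuleList:
    """Induce a CN2 rule list; see module docstring for the two variants."""
    y = np.asarray(labels).astype(str)
    classes = [str(c) for c in np.unique(y)]
    counts = {c: int((y == c).sum()) for c in classes}
    default = max(classes, key=lambda c: (counts[c], c))
    if len(classes) < 2:
        return RuleList([Rule((), classes[0], (counts[classes[0]], 0))],
                        variant, classes[0], (classes[0], classes[0]))

    rules: list[Rule] = []
    uncovered: dict[str, int] = {}

    def full_coverage(conds: tuple[Condition, ...], cls: str) -> tuple[int, int]:
        mask = Rule(conds, cls, (0, 0)).matches(frame)
        correct = int((mask & (y == cls)).sum())
        return correct, int(mask.sum()) - correct

    if variant == "unordered":
        for cls in classes:
            weights = np.ones(len(frame))
            prior = _laplace(counts[cls], len(y))
            while True:
                n_pos = int(((y == cls) & (weights > 0)).sum())
                if n_pos < min_coverage:
                    break
                found = _find_best_rule(frame, y, cls, weights, beam_width, max_conditions)
                if found is None:
                    break
                conds, q = found
                if not conds or q <= prior:
                    break
                correct, incorrect = full_coverage(conds, cls)
                if correct < min_coverage:
                    break
                rule = Rule(conds, cls, (correct, incorrect))
                rules.append(rule)
                covered = rule.matches(frame)
                weights[covered & (y == cls)] = 0.0  # keep negatives in play
            uncovered[cls] = int(((y == cls) & (weights > 0)).sum())
    elif variant == "ordered":
        weights = np.ones(len(frame))
        while weights.sum() > 0:
            rem_counts = {c: int(((y == c) & (weights > 0)).sum()) for c in classes}
            best_cls, found_best = None, None
            for cls in classes:
                if rem_counts[cls] == 0:
                    continue
                found = _find_best_rule(frame, y, cls, weights, beam_width, max_conditions)
                if found and (found_best is None or found[1] > found_best[1] + 1e-12):
                    best_cls, found_best = cls, found
            if found_best is None or not found_best[0]:
                break
            conds, _q = found_best
            mask = Rule(conds, best_cls, (0, 0)).matches(frame) & (weights > 0)
            correct = int((mask & (y == best_cls)).sum())
            if correct < min_coverage:
                break
            rules.append(Rule(conds, best_cls, (correct, int(mask.sum()) - correct)))
            weights[mask] = 0.0
        rem = {c: int(((y == c) & (weights > 0)).sum()) for c in classes}
        tail_default = max(classes, key=lambda c: (rem[c], c)) if weights.sum() else default
        rules.append(Rule((), tail_default,
                          (rem.get(tail_default, 0),
                           int(sum(rem.values())) - rem.get(tail_default, 0))))
        uncovered = {c: 0 for c in classes}
    else:
        raise ValueError(f"unknown CN2 variant {variant!r}")

    return RuleList(rules, variant, default, tuple(classes[:2]), uncovered)


def cn2_predict(rule_list: RuleList, frame: pd.DataFrame) -> np.ndarray:
    """Predict classes for each row of ``frame``."""
    n = len(frame)
    out = np.array([rule_list.default_class] * n, dtype=object)
    if rule_list.variant == "ordered":
        assigned = np.zeros(n, dtype=bool)
        for rule in rule_list.rules:
            mask = rule.matches(frame) & ~assigned
            out[mask] = rule.predicted_class
            assigned |= mask
        return out
    votes: dict[str, np.ndarray] = {}
    for rule in rule_list.rules:
        mask = rule.matches(frame)
        v = votes.setdefault(rule.predicted_class, np.zeros(n))
        v[mask] += rule.coverage[0]
    if votes:
        classes = sorted(votes)
        stack = np.vstack([votes[c] for c in classes])
        any_match = stack.sum(axis=0) > 0
        winner = np.argmax(stack, axis=0)
        out[any_match] = np.array(classes, dtype=object)[winner[any_match]]
    return out
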