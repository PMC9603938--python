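"""Banding-sequence algebra for polytene chromosome arms.

A chromosome arm's banding sequence is modelled as a permutation of labeled
band *fragments* relative to a group-standard reference.  Paracentric
inversions act on the sequence as unsigned reversals of a contiguous
interval of fragments: the printed cytological notation carries no
orientation marks on individual fragments, so fragments are atomic and
unsigned throughout (a signed, Hannenhalli-Pevzner-style model is out of
scope).

The module provides

* parsing of banding strings and of multi-line inversion-scenario notation
  (brackets mark the inverted interval, slashes are cosmetic breakpoint
  markers),
* application and verification of inversion scenarios,
* breakpoint counting against a reference (with virtual terminal caps so
  terminal rearrangements are counted; adjacency is orientation-free),
* exact minimal-inversion-distance search (iterative-deepening A* with the
  admissible lower bound ceil(breakpoints / 2)), and
* scenario search constrained to contain required, content-addressed steps.

Coordinates are 1-based inclusive, matching cytological convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil
from typing import Iterable, Optional, Sequence

ARM_IDS = ("IS", "IL", "IIS", "IIL", "IIIS", "IIIL")

#: Default search-node budget for the branch-and-bound distance search.
DEFAULT_NODE_BUDGET = 5_000_000


class BandingError(ValueError):
    """Invalid banding sequence, notation, or operation."""


class NodeBudgetExceeded(BandingError):
    """The distance search exhausted its node budget.

    The partial result (certified bound interval) is attached to the
    exception by the caller-facing API rather than raised, except for the
    constrained search where no certificate exists.
    """


class ConstraintUnsatisfiable(BandingError):
    """No scenario containing all required steps was found within budget."""


@dataclass(frozen=True)
class BandingSequence:
    """Ordered fragments of one chromosome arm relative to a group standard.

    Fragments are represented by their labels (short non-empty strings,
    e.g. ``"a"``..``"r"``); labels must be unique within a sequence.
    """

    arm_id: str
    fragments: tuple[str, ...]
    reference_name: str = "annulus-group standard"

    def __post_init__(self) -> None:
        if len(self.fragments) < 1:
            raise BandingError("banding sequence must contain at least one fragment")
        if any(not f for f in self.fragments):
            raise BandingError("fragment labels must be non-empty")
        if len(set(self.fragments)) != len(self.fragments):
            seen: set[str] = set()
            for i, f in enumerate(self.fragments, start=1):
                if f in seen:
                    raise BandingError(f"duplicate fragment label {f!r} at position {i}")
                seen.add(f)

    def __len__(self) -> int:
        return len(self.fragments)

    def __str__(self) -> str:
        if all(len(f) == 1 for f in self.fragments):
            return "".join(self.fragments)
        return ",".join(self.fragments)

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.fragments)


@dataclass(frozen=True)
class InversionStep:
    """One paracentric inversion: reverse positions start..end (1-based, inclusive)."""

    start: int
    end: int
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise BandingError(f"invalid inversion interval ({self.start}, {self.end})")


@dataclass
class Scenario:
    """An ordered list of inversion steps with the states they produce.

    ``intermediates[k]`` is the sequence after applying steps ``0..k`` to
    ``start_seq``; the last intermediate is the scenario's end state.
    """

    steps: list[InversionStep]
    start_seq: BandingSequence
    intermediates: list[BandingSequence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    @property
    def end_seq(self) -> BandingSequence:
        return self.intermediates[-1] if self.intermediates else self.start_seq

    def render(self) -> list[str]:
        """Render as bracket notation, one line per step plus a final state line."""
        lines = []
        state = self.start_seq
        for step in self.steps:
            frs = state.fragments
            name = (step.name + ": ") if step.name else ""
            body = (
                "".join(frs[: step.start - 1])
                + "["
                + "".join(frs[step.start - 1 : step.end])
                + "]"
                + "".join(frs[step.end :])
            )
            lines.append(name + body)
            state = apply_inversion(state, step)
        lines.append("".join(state.fragments))
        return lines


@dataclass
class VerificationReport:
    ok: bool
    first_mismatch: Optional[int]  # 1-based step index, or None
    intermediates: list[BandingSequence]


@dataclass
class DistanceResult:
    """Result of a minimal-inversion-distance search.

    When ``exact`` is False the node budget was exhausted and only the
    certified interval [lower_bound, upper_bound] is known.
    """

    distance: Optional[int]
    scenarios: list[Scenario]
    exact: bool
    lower_bound: int
    upper_bound: int
    nodes: int


# ---------------------------------------------------------------------------
# Parsing


def _tokenize(text: str) -> list[str]:
    """Split a banding string into labels.

    Comma-separated text yields multi-character labels; otherwise every
    alphanumeric character is a single-character label.  Whitespace and
    slashes (cosmetic breakpoint markers) are ignored.
    """
    cleaned = "".join(ch for ch in text if not ch.isspace() and ch != "/")
    if "," in cleaned:
        return [t for t in cleaned.split(",") if t]
    return list(cleaned)


def parse_banding(
    text: str,
    reference_labels: Iterable[str],
    arm_id: str = "IIL",
    reference_name: str = "annulus-group standard",
) -> BandingSequence:
    """Parse a banding string and validate it as a permutation of ``reference_labels``.

    Raises :class:`BandingError` on unknown, duplicate, or missing labels,
    reporting the 1-based fragment position of the offense.
    """
    ref = set(reference_labels)
    tokens = _tokenize(text)
    seen: set[str] = set()
    for pos, tok in enumerate(tokens, start=1):
        if tok not in ref:
            raise BandingError(f"unknown label {tok!r} at position {pos}")
        if tok in seen:
            raise BandingError(f"duplicate label {tok!r} at position {pos}")
        seen.add(tok)
    missing = ref - seen
    if missing:
        raise BandingError(f"missing labels: {sorted(missing)}")
    return BandingSequence(arm_id=arm_id, fragments=tuple(tokens), reference_name=reference_name)


def apply_inversion(seq: BandingSequence, step: InversionStep) -> BandingSequence:
    """Reverse fragments in positions start..end; positions are 1-based inclusive."""
    n = len(seq)
    if step.end > n:
        raise BandingError(f"inversion interval ({step.start}, {step.end}) out of bounds for length {n}")
    i, j = step.start - 1, step.end
    frs = seq.fragments
    return replace(seq, fragments=frs[:i] + tuple(reversed(frs[i:j])) + frs[j:])


def apply_scenario(seq: BandingSequence, scenario: Scenario) -> BandingSequence:
    for step in scenario.steps:
        seq = apply_inversion(seq, step)
    return seq


def parse_scenario_notation(
    lines: Sequence[str],
    arm_id: str = "IIL",
    reference_name: str = "annulus-group standard",
) -> Scenario:
    """Parse multi-line bracket/slash inversion notation into a :class:`Scenario`.

    Each step line contains exactly one bracketed segment marking the
    interval inverted to produce the next line; an optional ``name:`` prefix
    names the step.  Slashes mark breakpoints and are ignored for content.
    A final bracket-free line, if present, states the end state and is
    checked for consistency.  Consecutive lines must agree: line k+1's
    content must equal line k's content after applying line k's inversion.
    """
    parsed: list[tuple[Optional[str], Optional[InversionStep], tuple[str, ...]]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        name: Optional[str] = None
        if ":" in line:
            name_part, line = line.rsplit(":", 1)
            name = name_part.strip().strip("*").strip() or None
        n_open, n_close = line.count("["), line.count("]")
        if n_open != n_close or n_open > 1:
            raise BandingError(f"line {lineno}: unbalanced or multiple brackets")
        if n_open == 1 and line.index("[") > line.index("]"):
            raise BandingError(f"line {lineno}: unbalanced brackets")
        if n_open == 0:
            tokens = _tokenize(line)
            if not tokens:
                raise BandingError(f"line {lineno}: empty sequence")
            parsed.append((name, None, tuple(tokens)))
            continue
        pre, rest = line.split("[", 1)
        inside, post = rest.split("]", 1)
        pre_t, in_t, post_t = _tokenize(pre), _tokenize(inside), _tokenize(post)
        if not in_t:
            raise BandingError(f"line {lineno}: empty bracketed segment")
        start = len(pre_t) + 1
        end = start + len(in_t) - 1
        step = InversionStep(start=start, end=end, name=name)
        parsed.append((name, step, tuple(pre_t + in_t + post_t)))

    if not parsed:
        raise BandingError("no scenario lines")
    step_entries = [(s, frs) for (_, s, frs) in parsed if s is not None]
    if not step_entries:
        raise BandingError("scenario contains no bracketed step lines")
    for k, (_, s, frs) in enumerate(parsed):
        if s is None and k != len(parsed) - 1:
            raise BandingError(f"line {k + 1}: bracket-free line allowed only as final state")

    ref_labels = set(parsed[0][2])
    start_seq = BandingSequence(arm_id=arm_id, fragments=parsed[0][2], reference_name=reference_name)
    steps: list[InversionStep] = []
    intermediates: list[BandingSequence] = []
    state = start_seq
    for k, (_, step, frs) in enumerate(parsed):
        if set(frs) != ref_labels:
            raise BandingError(f"line {k + 1}: label set differs from first line")
        if state.fragments != frs:
            raise BandingError(
                f"line {k + 1}: sequence {''.join(frs)} inconsistent with applying "
                f"previous inversion (expected {''.join(state.fragments)})"
            )
        if step is None:
            break
        steps.append(step)
        state = apply_inversion(state, step)
        intermediates.append(state)
    return Scenario(steps=steps, start_seq=start_seq, intermediates=intermediates)


def verify_scenario(
    start: BandingSequence, scenario: Scenario, target: BandingSequence
) -> VerificationReport:
    """Replay ``scenario`` from ``start`` and check the result equals ``target``.

    ``first_mismatch`` is the 1-based index of the first step whose result
    disagrees with the scenario's recorded intermediates (when present);
    intermediates of the replay are returned for display regardless.
    """
    if start.labels != target.labels:
        raise BandingError("start and target are over different label sets")
    state = start
    intermediates: list[BandingSequence] = []
    first_mismatch: Optional[int] = None
    for k, step in enumerate(scenario.steps, start=1):
        state = apply_inversion(state, step)
        intermediates.append(state)
        if (
            first_mismatch is None
            and k <= len(scenario.intermediates)
            and state.fragments != scenario.intermediates[k - 1].fragments
        ):
            first_mismatch = k
    ok = state.fragments == target.fragments
    if not ok and first_mismatch is None:
        first_mismatch = len(scenario.steps) if scenario.steps else 0
    return VerificationReport(ok=ok, first_mismatch=None if ok else first_mismatch, intermediates=intermediates)


# ---------------------------------------------------------------------------
# Breakpoints and distance


def _as_ints(seq: BandingSequence, ref: BandingSequence) -> tuple[int, ...]:
    """Relabel seq by the 0-based position of each fragment in ref."""
    if seq.labels != ref.labels:
        raise BandingError("sequences are over different label sets")
    index = {f: i for i, f in enumerate(ref.fragments)}
    return tuple(index[f] for f in seq.fragments)


def _breakpoints_int(perm: Sequence[int]) -> int:
    """Unsigned breakpoints of an integer permutation against the identity.

    Virtual terminal caps are adjacent to both identity ends (0 and n-1), so
    the full reversal of the identity also has zero breakpoints; adjacency is
    orientation-free: |x - y| == 1.
    """
    n = len(perm)
    b = 0
    if perm[0] not in (0, n - 1):
        b += 1
    for x, y in zip(perm, perm[1:]):
        if abs(x - y) != 1:
            b += 1
    if perm[-1] not in (0, n - 1):
        b += 1
    return b


def breakpoint_count(seq: BandingSequence, ref: BandingSequence) -> int:
    """Number of neighbor pairs of ``seq`` (with virtual framing ends) not adjacent in ``ref``."""
    return _breakpoints_int(_as_ints(seq, ref))


def _search_moves(n: int):
    return [(i, j) for i in range(n - 1) for j in range(i + 1, n)]


def _delta_b(perm: tuple[int, ...], i: int, j: int, n: int) -> int:
    """Change in breakpoint count caused by reversing perm[i..j] (0-based, inclusive)."""

    def notadj(u: int, v: int) -> int:
        if u < 0:  # cap
            return 0 if v in (0, n - 1) else 1
        if v < 0:
            return 0 if u in (0, n - 1) else 1
        return 0 if abs(u - v) == 1 else 1

    left = perm[i - 1] if i > 0 else -1
    right = perm[j + 1] if j < n - 1 else -1
    old = notadj(left, perm[i]) + notadj(perm[j], right)
    new = notadj(left, perm[j]) + notadj(perm[i], right)
    return new - old


def _ida_search(
    start: tuple[int, ...],
    node_budget: int,
    max_scenarios: int,
    required: Optional[list[frozenset[int]]] = None,
) -> tuple[Optional[int], list[list[tuple[int, int]]], int, bool]:
    """Iterative-deepening A* for unsigned sorting by reversals.

    Returns (distance, solution move-lists (0-based, inclusive), nodes used,
    budget_ok).  ``required`` constrains solutions to contain, for each
    listed fragment-content set, a move whose reversed segment carries
    exactly that content; the heuristic is then
    max(ceil(b/2), #unsatisfied requirements), still admissible because a
    single move can both remove two breakpoints and satisfy a requirement.
    """
    n = len(start)
    goal = tuple(range(n))
    nreq = len(required) if required else 0
    full_mask = (1 << nreq) - 1
    req_sets = required or []

    b0 = _breakpoints_int(start)

    def h(b: int, mask: int) -> int:
        miss = nreq - bin(mask).count("1")
        return max((b + 1) // 2, miss)

    if start == goal and full_mask == 0:
        return 0, [[]], 0, True

    moves = _search_moves(n)
    nodes = 0
    budget_ok = True
    limit = h(b0, 0)
    while True:
        solutions: list[list[tuple[int, int]]] = []
        next_limit = [None]
        # transposition table: (perm, mask) -> shallowest depth seen this iteration
        tt: dict[tuple, int] = {}

        def dfs(perm: tuple[int, ...], b: int, mask: int, depth: int, path: list) -> bool:
            nonlocal nodes, budget_ok
            if perm == goal and mask == full_mask:
                solutions.append(list(path))
                return len(solutions) >= max_scenarios
            for (i, j) in moves:
                nodes += 1
                if nodes > node_budget:
                    budget_ok = False
                    return True
                db = _delta_b(perm, i, j, n)
                nb = b + db
                seg = perm[i : j + 1]
                nmask = mask
                if nreq:
                    content = frozenset(seg)
                    for r, rs in enumerate(req_sets):
                        if not (mask >> r) & 1 and content == rs:
                            nmask = mask | (1 << r)
                            break
                f = depth + 1 + h(nb, nmask)
                if f > limit:
                    if next_limit[0] is None or f < next_limit[0]:
                        next_limit[0] = f
                    continue
                child = perm[:i] + seg[::-1] + perm[j + 1 :]
                key = (child, nmask)
                prev = tt.get(key)
                if prev is not None and (prev < depth + 1 or (max_scenarios == 1 and prev <= depth + 1)):
                    continue
                tt[key] = depth + 1
                path.append((i, j))
                stop = dfs(child, nb, nmask, depth + 1, path)
                path.pop()
                if stop:
                    return True
            return False

        dfs(start, b0, 0, 0, [])
        if solutions:
            return limit, solutions, nodes, budget_ok
        if not budget_ok or next_limit[0] is None:
            return None, [], nodes, budget_ok
        limit = next_limit[0]


def _moves_to_scenario(
    seq: BandingSequence, moves: list[tuple[int, int]]
) -> Scenario:
    steps = [InversionStep(start=i + 1, end=j + 1) for (i, j) in moves]
    sc = Scenario(steps=steps, start_seq=seq, intermediates=[])
    state = seq
    for step in steps:
        state = apply_inversion(state, step)
        sc.intermediates.append(state)
    return sc


def greedy_upper_bound(perm: tuple[int, ...], max_iter: int = 10_000) -> int:
    """Length of a breakpoint-greedy sorting sequence (an upper bound on distance)."""
    n = len(perm)
    goal = tuple(range(n))
    k = 0
    while perm != goal and k < max_iter:
        b = _breakpoints_int(perm)
        best = None
        for (i, j) in _search_moves(n):
            db = _delta_b(perm, i, j, n)
            cand = perm[:i] + perm[i : j + 1][::-1] + perm[j + 1 :]
            if cand == goal:
                return k + 1
            if best is None or db < best[0]:
                best = (db, i, j)
        db, i, j = best
        perm = perm[:i] + perm[i : j + 1][::-1] + perm[j + 1 :]
        k += 1
    return k


def min_inversion_distance(
    seq: BandingSequence,
    ref: BandingSequence,
    max_scenarios: int = 1,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> DistanceResult:
    """Minimum number of unsigned reversals transforming ``seq`` into ``ref``.

    Iterative-deepening branch-and-bound with the admissible lower bound
    ceil(breakpoints / 2); up to ``max_scenarios`` optimal scenarios are
    returned, enumerated in lexicographic move order.  If the node budget is
    exhausted, the result carries ``exact=False`` and a certified interval
    [ceil(b/2), greedy upper bound].
    """
    perm = _as_ints(seq, ref)
    b = _breakpoints_int(perm)
    lb = (b + 1) // 2
    dist, move_lists, nodes, budget_ok = _ida_search(perm, node_budget, max_scenarios)
    if dist is not None and budget_ok:
        scenarios = [_moves_to_scenario(seq, m) for m in move_lists]
        return DistanceResult(
            distance=dist, scenarios=scenarios, exact=True,
            lower_bound=dist, upper_bound=dist, nodes=nodes,
        )
    ub = greedy_upper_bound(perm)
    return DistanceResult(
        distance=None, scenarios=[], exact=False,
        lower_bound=lb, upper_bound=ub, nodes=nodes,
    )


def constrained_scenario_search(
    seq: BandingSequence,
    ref: BandingSequence,
    required: Sequence[tuple[Optional[str], Iterable[str]]],
    max_scenarios: int = 1,
    node_budget: int = DEFAULT_NODE_BUDGET,
) -> DistanceResult:
    """Shortest scenarios from ``seq`` to ``ref`` containing all required steps.

    Each requirement is (name, fragment labels): some step of the scenario
    must invert a contiguous segment whose fragment content equals exactly
    that label set (content-addressed, since positions shift between
    states).  Raises :class:`ConstraintUnsatisfiable` if no such scenario is
    found within the node budget.
    """
    perm = _as_ints(seq, ref)
    index = {f: i for i, f in enumerate(ref.fragments)}
    req_sets: list[frozenset[int]] = []
    names: list[Optional[str]] = []
    for name, labels in required:
        labels = list(labels)
        unknown = [l for l in labels if l not in index]
        if unknown or not labels:
            raise BandingError(f"required step {name!r}: unknown or empty content {unknown}")
        req_sets.append(frozenset(index[l] for l in labels))
        names.append(name)
    dist, move_lists, nodes, budget_ok = _ida_search(
        perm, node_budget, max_scenarios, required=req_sets
    )
    if dist is None or not budget_ok:
        raise ConstraintUnsatisfiable(
            f"no scenario containing all {len(req_sets)} required steps found "
            f"within {node_budget} nodes"
        )
    scenarios = []
    for mv in move_lists:
        sc = _moves_to_scenario(seq, mv)
        # attach requirement names to the steps that satisfied them
        state = seq
        satisfied = [False] * len(req_sets)
        new_steps = []
        for step in sc.steps:
            content = frozenset(index[f] for f in state.fragments[step.start - 1 : step.end])
            name = None
            for r, rs in enumerate(req_sets):
                if not satisfied[r] and content == rs:
                    satisfied[r] = True
                    name = names[r]
                    break
            new_steps.append(replace(step, name=name))
            state = apply_inversion(state, step)
        sc.steps = new_steps
        scenarios.append(sc)
    return DistanceResult(
        distance=dist, scenarios=scenarios, exact=True,
        lower_bound=dist, upper_bound=dist, nodes=nodes,
    )
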