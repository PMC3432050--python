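"""Finite-state (Markov-chain) artificial grammar engine.

A grammar is a directed labeled automaton: a sequence of syllables is
*grammatical* iff some path of arcs from the entry ("In") state consumes
exactly the sequence and ends in an exit ("Out") state.  The engine
generates the study and test lists of the classic artificial-grammar
learning (AGL) paradigm: grammatical study sequences of two to five
syllables presented in increasing length, and a grammaticality-judgment
test list of novel grammatical items and length-matched ungrammatical
foils.

Acceptance is nondeterministic: the full set of reachable states is
tracked per position, so grammars with ambiguous (state, syllable) arcs
are handled correctly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Grammar",
    "SyllableSequence",
    "StudyList",
    "TestItem",
    "GrammarError",
    "CapacityError",
    "PerturbationError",
    "load_grammar",
    "default_grammar",
    "accepts",
    "enumerate_grammatical",
    "make_ungrammatical",
    "build_study_list",
    "build_test_list",
]

MIN_SEQ_LEN = 2
MAX_SEQ_LEN = 5
ENUMERATION_GUARD = 12  # hard cap on enumeration length (loop explosion)

VIOLATION_RULES = ("off_path_substitution", "syllable_deletion")


class GrammarError(ValueError):
    """Malformed or invalid grammar specification."""


class CapacityError(ValueError):
    """The grammar cannot supply enough distinct sequences."""


class PerturbationError(ValueError):
    """No valid ungrammatical perturbation exists."""


@dataclass(frozen=True)
class SyllableSequence:
    """An ordered syllable string with a grammaticality label."""

    syllables: tuple[str, ...]
    label: str = "unknown"  # grammatical | ungrammatical | unknown

    def __post_init__(self) -> None:
        if self.label not in ("grammatical", "ungrammatical", "unknown"):
            raise ValueError(f"unknown label {self.label!r}")
        object.__setattr__(self, "syllables", tuple(self.syllables))

    def __len__(self) -> int:
        return len(self.syllables)

    def __str__(self) -> str:
        return " ".join(self.syllables)

    @classmethod
    def from_string(cls, text: str, label: str = "unknown") -> "SyllableSequence":
        return cls(tuple(text.split()), label)


@dataclass(frozen=True)
class Grammar:
    """Directed labeled automaton defining the sequence language."""

    states: frozenset[str]
    arcs: frozenset[tuple[str, str, str]]  # (from_state, syllable, to_state)
    in_state: str
    out_states: frozenset[str]

    @property
    def alphabet(self) -> frozenset[str]:
        return frozenset(syl for _, syl, _ in self.arcs)

    def transitions(self) -> Mapping[str, list[tuple[str, str]]]:
        """state -> list of (syllable, next_state), deterministically ordered."""
        table: dict[str, list[tuple[str, str]]] = {s: [] for s in self.states}
        for frm, syl, to in sorted(self.arcs):
            table[frm].append((syl, to))
        return table

    def validate(self) -> None:
        if self.in_state not in self.states:
            raise GrammarError(f"in state {self.in_state!r} not declared in states")
        if not self.out_states:
            raise GrammarError("out states must be nonempty")
        for out in self.out_states:
            if out not in self.states:
                raise GrammarError(f"out state {out!r} not declared in states")
        for frm, syl, to in self.arcs:
            for ref, role in ((frm, "from"), (to, "to")):
                if ref not in self.states:
                    raise GrammarError(
                        f"arc ({frm!r}, {syl!r}, {to!r}) references "
                        f"undeclared {role} state {ref!r}"
                    )
        table = self.transitions()
        if not table[self.in_state]:
            raise GrammarError(f"in state {self.in_state!r} has no outgoing arc")
        # every out state reachable from in_state
        seen = {self.in_state}
        frontier = [self.in_state]
        while frontier:
            state = frontier.pop()
            for _, nxt in table[state]:
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        unreachable = self.out_states - seen
        if unreachable:
            raise GrammarError(
                f"out state(s) {sorted(unreachable)} unreachable from "
                f"{self.in_state!r}"
            )


def load_grammar(source: str | Path | Mapping) -> Grammar:
    """Load and validate a grammar from a JSON document or parsed mapping.

    The document declares ``states`` (list), ``in`` (single entry state),
    ``out`` (list of exit states) and ``arcs`` (list of
    ``[from, syllable, to]`` triples).
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        try:
            doc = json.loads(Path(source).read_text())
        except json.JSONDecodeError as exc:
            raise GrammarError(f"grammar document is not valid JSON: {exc}") from exc
    for key in ("states", "in", "out", "arcs"):
        if key not in doc:
            raise GrammarError(f"grammar document missing field {key!r}")
    arcs = []
    for arc in doc["arcs"]:
        if len(arc) != 3 or not all(isinstance(x, str) for x in arc):
            raise GrammarError(f"malformed arc entry {arc!r} in field 'arcs'")
        arcs.append(tuple(arc))
    g = Grammar(
        states=frozenset(doc["states"]),
        arcs=frozenset(arcs),
        in_state=doc["in"],
        out_states=frozenset(doc["out"]),
    )
    g.validate()
    return g


def default_grammar() -> Grammar:
    """The packaged default grammar (Reber-style two-branch/loop topology)."""
    with resources.files("aglnet.data").joinpath("default_grammar.json").open() as fh:
        return load_grammar(json.load(fh))


def _step(g: Grammar, states: frozenset[str], syllable: str) -> frozenset[str]:
    return frozenset(to for frm, syl, to in g.arcs if frm in states and syl == syllable)


def accepts(g: Grammar, s: SyllableSequence | Sequence[str] | str) -> bool:
    """True iff some In-to-Out path emits exactly the sequence.

    Subset construction over reachable states; unknown syllables simply
    empty the reachable set and force rejection.  The empty sequence is
    rejected (no arc traversed, no syllable emitted).
    """
    syllables = _as_syllables(s)
    if not syllables:
        return False
    reach = frozenset([g.in_state])
    for syl in syllables:
        reach = _step(g, reach, syl)
        if not reach:
            return False
    return bool(reach & g.out_states)


def _as_syllables(s: SyllableSequence | Sequence[str] | str) -> tuple[str, ...]:
    if isinstance(s, SyllableSequence):
        return s.syllables
    if isinstance(s, str):
        return tuple(s.split())
    return tuple(s)


def enumerate_grammatical(
    g: Grammar, min_len: int, max_len: int
) -> list[SyllableSequence]:
    """All grammatical sequences with length in [min_len, max_len].

    Ordered by length, then lexicographically by syllables.  Lengths are
    capped at 12 to guard against loop explosion.
    """
    if not (1 <= min_len <= max_len):
        raise ValueError(f"need 1 <= min_len <= max_len, got {min_len}, {max_len}")
    if max_len > ENUMERATION_GUARD:
        raise ValueError(
            f"max_len {max_len} exceeds enumeration guard {ENUMERATION_GUARD}"
        )
    table = g.transitions()
    found: set[tuple[str, ...]] = set()
    # depth-first over paths; distinct emitted strings are deduplicated
    stack: list[tuple[str, tuple[str, ...]]] = [(g.in_state, ())]
    while stack:
        state, prefix = stack.pop()
        for syl, nxt in table[state]:
            emitted = prefix + (syl,)
            if nxt in g.out_states and min_len <= len(emitted) <= max_len:
                found.add(emitted)
            if len(emitted) < max_len:
                stack.append((nxt, emitted))
    ordered = sorted(found, key=lambda t: (len(t), t))
    return [SyllableSequence(t, "grammatical") for t in ordered]


def make_ungrammatical(
    g: Grammar,
    s: SyllableSequence,
    rule: str = "off_path_substitution",
    seed: int | np.random.Generator = 0,
) -> SyllableSequence:
    """Perturb a grammatical sequence into an ungrammatical foil.

    ``off_path_substitution`` replaces one syllable with one that no state
    reachable at that position allows, guaranteeing rejection analytically
    and preserving length.  ``syllable_deletion`` removes one syllable
    (result must still be rejected and at least two syllables long).
    """
    if rule not in VIOLATION_RULES:
        raise ValueError(f"rule must be one of {VIOLATION_RULES}, got {rule!r}")
    if not accepts(g, s):
        raise ValueError("input sequence must be grammatical")
    rng = np.random.default_rng(seed)
    syllables = _as_syllables(s)
    alphabet = sorted(g.alphabet)
    n = len(syllables)

    if rule == "off_path_substitution":
        # reachable state set before each position
        reach = frozenset([g.in_state])
        reach_at = []
        for syl in syllables:
            reach_at.append(reach)
            reach = _step(g, reach, syl)
        candidates: list[tuple[int, str]] = []
        for i in range(n):
            allowed = {syl for frm, syl, _ in g.arcs if frm in reach_at[i]}
            for alt in alphabet:
                if alt not in allowed:
                    candidates.append((i, alt))
        # off-path syllables can be unavailable (dense grammars); fall back
        # to any single substitution the acceptance oracle rejects
        if not candidates:
            for i in range(n):
                for alt in alphabet:
                    if alt == syllables[i]:
                        continue
                    edited = syllables[:i] + (alt,) + syllables[i + 1 :]
                    if not accepts(g, edited):
                        candidates.append((i, alt))
        if not candidates:
            raise PerturbationError(
                f"no rejecting substitution exists for {' '.join(syllables)!r}"
            )
        i, alt = candidates[rng.integers(len(candidates))]
        out = syllables[:i] + (alt,) + syllables[i + 1 :]
        return SyllableSequence(out, "ungrammatical")

    # syllable_deletion
    positions = list(rng.permutation(n))
    for i in positions:
        edited = syllables[:i] + syllables[i + 1 :]
        if len(edited) >= MIN_SEQ_LEN and not accepts(g, edited):
            return SyllableSequence(edited, "ungrammatical")
    raise PerturbationError(
        f"no rejecting deletion of length >= {MIN_SEQ_LEN} exists for "
        f"{' '.join(syllables)!r}"
    )


@dataclass(frozen=True)
class StudyList:
    """Ordered study-phase presentations of grammatical sequences."""

    items: tuple[SyllableSequence, ...]
    unique_count: int
    repetitions: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))

    @property
    def unique_sequences(self) -> set[tuple[str, ...]]:
        return {item.syllables for item in self.items}


@dataclass(frozen=True)
class TestItem:
    __test__ = False  # not a pytest class despite the name

    sequence: SyllableSequence
    truth: bool  # True = grammatical
    matched_length: int


def build_study_list(
    g: Grammar,
    unique_count: int = 22,
    repetitions: int = 3,
    seed: int = 0,
) -> StudyList:
    """Sample the study list: distinct grammatical sequences of length 2-5,
    presented in nondecreasing length within each pass, with ``repetitions``
    passes in total (the default 22 x 3 = 66 presentations).

    Sampling is stratified round-robin across lengths so every available
    length stratum is represented.
    """
    rng = np.random.default_rng(seed)
    pool = enumerate_grammatical(g, MIN_SEQ_LEN, MAX_SEQ_LEN)
    if len(pool) < unique_count:
        raise CapacityError(
            f"grammar yields only {len(pool)} distinct sequences of length "
            f"{MIN_SEQ_LEN}-{MAX_SEQ_LEN}; {unique_count} requested"
        )
    by_length: dict[int, list[SyllableSequence]] = {}
    for seq in pool:
        by_length.setdefault(len(seq), []).append(seq)
    for stratum in by_length.values():
        rng.shuffle(stratum)  # in-place, deterministic under the seed
    chosen: list[SyllableSequence] = []
    lengths = sorted(by_length)
    while len(chosen) < unique_count:
        progressed = False
        for length in lengths:
            if by_length[length] and len(chosen) < unique_count:
                chosen.append(by_length[length].pop())
                progressed = True
        if not progressed:  # pragma: no cover - guarded by pool size check
            break
    one_pass = sorted(chosen, key=lambda s: (len(s), s.syllables))
    items = tuple(one_pass) * repetitions
    return StudyList(items=items, unique_count=unique_count, repetitions=repetitions)


def build_test_list(
    g: Grammar,
    study: StudyList,
    n_items: int = 48,
    seed: int = 0,
) -> list[TestItem]:
    """Build the grammaticality-judgment test list.

    Half the items are novel grammatical sequences (absent from the study
    list), half are ungrammatical foils produced by off-path substitution
    from grammatical templates; the two halves have identical length
    distributions.  Items are shuffled deterministically under the seed.
    """
    rng = np.random.default_rng(seed)
    n_gram = n_items // 2
    n_foil = n_items - n_gram
    studied = study.unique_sequences
    novel = [
        seq
        for seq in enumerate_grammatical(g, MIN_SEQ_LEN, MAX_SEQ_LEN)
        if seq.syllables not in studied
    ]
    if len(novel) < n_gram:
        raise CapacityError(
            f"only {len(novel)} novel grammatical sequences available; "
            f"{n_gram} needed"
        )
    idx = rng.permutation(len(novel))[:n_gram]
    gram_items = [novel[i] for i in sorted(idx)]

    # foils: one per grammatical item length, substitution preserves length
    templates = enumerate_grammatical(g, MIN_SEQ_LEN, MAX_SEQ_LEN)
    by_length: dict[int, list[SyllableSequence]] = {}
    for seq in templates:
        by_length.setdefault(len(seq), []).append(seq)
    foil_lengths = [len(s) for s in gram_items][:n_foil]
    foils: list[SyllableSequence] = []
    seen_foils: set[tuple[str, ...]] = set()
    for length in foil_lengths:
        made = None
        for attempt in range(200):
            template = by_length[length][rng.integers(len(by_length[length]))]
            foil = make_ungrammatical(
                g, template, "off_path_substitution", seed=rng.integers(2**31)
            )
            if foil.syllables not in seen_foils:
                made = foil
                break
        if made is None:
            raise CapacityError(
                f"could not generate a distinct length-{length} foil"
            )
        seen_foils.add(made.syllables)
        foils.append(made)

    items = [TestItem(s, True, len(s)) for s in gram_items] + [
        TestItem(s, False, len(s)) for s in foils
    ]
    order = rng.permutation(len(items))
    return [items[i] for i in order]


def study_list_to_rows(study: StudyList) -> list[dict]:
    """Delimited-text rows: index, phase, sequence, truth label."""
    return [
        {
            "index": i,
            "phase": "study",
            "sequence": str(item),
            "truth": "grammatical",
        }
        for i, item in enumerate(study.items)
    ]


def test_list_to_rows(items: Iterable[TestItem]) -> list[dict]:
    return [
        {
            "index": i,
            "phase": "test",
            "sequence": str(item.sequence),
            "truth": "grammatical" if item.truth else "ungrammatical",
        }
        for i, item in enumerate(items)
    ]
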