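"""Two-language, two-context word-learning design and the cued-reinstatement test schedule.

The design crosses two phonetically similar languages with two virtual
environments ("contexts").  A *dual-context* learner encodes each language in
its own context; a *single-context* learner encodes both languages in the same
context (the other context hosts no language and is only ever seen during
context encoding).  The short-delay test probes every learnt word once, in runs
of equal length, after cueing mental reinstatement of a room that is either
*congruent* (the word's learning context) or *incongruent* (the other context)
with the probed word.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VRContext",
    "GroupAssignment",
    "WordItem",
    "T4TrialSpec",
    "DEFAULT_CONTEXTS",
    "default_contexts",
    "build_word_design",
    "build_t4_schedule",
    "words_to_table",
    "schedule_to_table",
    "words_from_table",
    "schedule_from_table",
]

LANGUAGE_NAMES = {"L1": "Swahili", "L2": "Chinyanja"}

_MOON_ROOMS = (
    "Airlock", "Sickbay", "Command Deck", "Hydroponics", "Reactor Hall",
    "Crew Quarters", "Observatory", "Cargo Bay", "Communications",
)
_GARDEN_ROOMS = (
    "Lily Pond", "Willow Grove", "Mushroom Hollow", "Rose Arbor", "Fern Gully",
    "Wishing Well", "Toadstool Ring", "Lantern Walk", "Moss Bridge",
)


@dataclass(frozen=True)
class VRContext:
    """One virtual environment with its nine named rooms."""

    id: str  # "A" or "B"
    name: str
    rooms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.id not in ("A", "B"):
            raise ValueError(f"context id must be 'A' or 'B', got {self.id!r}")
        if len(self.rooms) != 9:
            raise ValueError(f"a context has exactly 9 rooms, got {len(self.rooms)}")
        if len(set(self.rooms)) != 9:
            raise ValueError("room names must be unique within a context")


@dataclass(frozen=True)
class GroupAssignment:
    """Which context hosts which language.

    ``group == "dual"`` maps the two languages to different contexts;
    ``group == "single"`` maps both to the same context.
    """

    group: str
    context_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("single", "dual"):
            raise ValueError(f"group must be 'single' or 'dual', got {self.group!r}")
        if set(self.context_of) != {"L1", "L2"}:
            raise ValueError("context_of must map exactly L1 and L2")
        distinct = self.context_of["L1"] != self.context_of["L2"]
        if self.group == "dual" and not distinct:
            raise ValueError("dual group requires distinct contexts per language")
        if self.group == "single" and distinct:
            raise ValueError("single group requires one shared context")


@dataclass(frozen=True)
class WordItem:
    item_id: str
    english_gloss: str
    language: str  # "L1" | "L2"
    shared: bool  # the English word is learnt in both languages
    learning_context: str  # VRContext id
    phoneme_count: int

    def __post_init__(self) -> None:
        if self.language not in ("L1", "L2"):
            raise ValueError(f"language must be 'L1' or 'L2', got {self.language!r}")
        if self.phoneme_count < 1:
            raise ValueError("phoneme_count must be positive")


@dataclass(frozen=True)
class T4TrialSpec:
    trial_index: int  # 1-based across the whole test
    run_index: int  # 1-based
    cued_context: str  # VRContext id
    cued_room: str
    probed_item: str  # item_id
    congruency: str  # "congruent" | "incongruent"


def default_contexts(swap: bool = False) -> tuple[VRContext, VRContext]:
    """The two default environments; ``swap`` counterbalances which is Context A."""
    moon = ("Moon Base", _MOON_ROOMS)
    garden = ("Fairyland Garden", _GARDEN_ROOMS)
    first, second = (garden, moon) if swap else (moon, garden)
    return (
        VRContext("A", first[0], first[1]),
        VRContext("B", second[0], second[1]),
    )


DEFAULT_CONTEXTS = default_contexts()

# Syllable inventories for deterministic pseudo-word generation.  Each
# character of a syllable counts as one phoneme, mirroring phoneme-level
# scoring of simple CV transliterations.
_ONSETS = "bcdfgjklmnprstvwyz"
_VOWELS = "aeiou"


def _gloss(rng: np.random.Generator, taken: set[str]) -> str:
    while True:
        n_syl = int(rng.integers(1, 3))
        word = "".join(
            _ONSETS[rng.integers(len(_ONSETS))] + _VOWELS[rng.integers(len(_VOWELS))]
            for _ in range(n_syl + 1)
        )
        if word not in taken:
            taken.add(word)
            return word


def _transliteration(rng: np.random.Generator) -> str:
    # 2-4 CV syllables -> 4-8 phonemes
    n_syl = int(rng.integers(2, 5))
    return "".join(
        _ONSETS[rng.integers(len(_ONSETS))] + _VOWELS[rng.integers(len(_VOWELS))]
        for _ in range(n_syl)
    )


def build_word_design(
    n_l1_only: int,
    n_l2_only: int,
    n_shared: int,
    group: str,
    seed: int,
) -> tuple[list[WordItem], GroupAssignment]:
    """Build the word design: items learnt in one language only plus shared items.

    Returns ``n_l1_only + n_l2_only + 2 * n_shared`` items (each shared English
    word contributes one item per language).  Glosses and pseudo-foreign
    transliterations are generated deterministically from ``seed``; a word's
    ``phoneme_count`` is its transliteration's phoneme count.
    """
    if min(n_l1_only, n_l2_only, n_shared) < 0:
        raise ValueError("counts must be non-negative")
    if n_l1_only + n_l2_only + n_shared == 0:
        raise ValueError("empty design")
    if group == "dual":
        assignment = GroupAssignment("dual", {"L1": "A", "L2": "B"})
    elif group == "single":
        assignment = GroupAssignment("single", {"L1": "A", "L2": "A"})
    else:
        raise ValueError(f"group must be 'single' or 'dual', got {group!r}")

    rng = np.random.default_rng(seed)
    taken: set[str] = set()
    items: list[WordItem] = []

    def add(gloss: str, language: str, shared: bool) -> None:
        items.append(
            WordItem(
                item_id=f"w{len(items) + 1:03d}_{language}",
                english_gloss=gloss,
                language=language,
                shared=shared,
                learning_context=assignment.context_of[language],
                phoneme_count=len(_transliteration(rng)),
            )
        )

    for _ in range(n_l1_only):
        add(_gloss(rng, taken), "L1", shared=False)
    for _ in range(n_l2_only):
        add(_gloss(rng, taken), "L2", shared=False)
    for _ in range(n_shared):
        gloss = _gloss(rng, taken)
        add(gloss, "L1", shared=True)
        add(gloss, "L2", shared=True)
    return items, assignment


def build_t4_schedule(
    words: list[WordItem],
    assignment: GroupAssignment,
    contexts: tuple[VRContext, VRContext],
    n_runs: int = 10,
    seed: int = 0,
) -> list[T4TrialSpec]:
    """Build the cued-reinstatement test schedule: each word probed exactly once.

    Congruency is balanced 50/50 within each language (the extra trial of an
    odd-sized language is congruent), trials are shuffled across the whole test
    by ``seed``, and the cued room is drawn uniformly from the cued context's
    nine rooms.  The schedule is a pure function of its arguments.
    """
    if n_runs < 1 or len(words) % n_runs != 0:
        raise ValueError("uneven runs")
    by_id = {c.id: c for c in contexts}
    if set(by_id) != {"A", "B"}:
        raise ValueError("contexts must be the A/B pair")
    rng = np.random.default_rng(seed)

    congruent_of: dict[str, bool] = {}
    for language in ("L1", "L2"):
        lang_items = [w.item_id for w in words if w.language == language]
        n_incong = len(lang_items) // 2
        incong = set(rng.choice(lang_items, size=n_incong, replace=False)) if n_incong else set()
        for item in lang_items:
            congruent_of[item] = item not in incong

    order = rng.permutation(len(words))
    per_run = len(words) // n_runs
    trials: list[T4TrialSpec] = []
    for pos, widx in enumerate(order):
        word = words[int(widx)]
        congruent = congruent_of[word.item_id]
        learning = word.learning_context
        cued = learning if congruent else ("B" if learning == "A" else "A")
        room = by_id[cued].rooms[int(rng.integers(9))]
        trials.append(
            T4TrialSpec(
                trial_index=pos + 1,
                run_index=pos // per_run + 1,
                cued_context=cued,
                cued_room=room,
                probed_item=word.item_id,
                congruency="congruent" if congruent else "incongruent",
            )
        )
    return trials


# ---------------------------------------------------------------------------
# tab-separated serialisation (field names match the dataclasses)

def words_to_table(words: list[WordItem]) -> pd.DataFrame:
    return pd.DataFrame([vars(w) for w in words])


def schedule_to_table(schedule: list[T4TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame([vars(t) for t in schedule])


def words_from_table(table: pd.DataFrame) -> list[WordItem]:
    return [
        WordItem(
            item_id=str(r.item_id),
            english_gloss=str(r.english_gloss),
            language=str(r.language),
            shared=bool(r.shared),
            learning_context=str(r.learning_context),
            phoneme_count=int(r.phoneme_count),
        )
        for r in table.itertuples()
    ]


def schedule_from_table(table: pd.DataFrame) -> list[T4TrialSpec]:
    return [
        T4TrialSpec(
            trial_index=int(r.trial_index),
            run_index=int(r.run_index),
            cued_context=str(r.cued_context),
            cued_room=str(r.cued_room),
            probed_item=str(r.probed_item),
            congruency=str(r.congruency),
        )
        for r in table.itertuples()
    ]


def design_fingerprint(words: list[WordItem], schedule: list[T4TrialSpec]) -> str:
    """Stable content hash used to stamp downstream outputs."""
    h = hashlib.sha256()
    h.update(words_to_table(words).to_csv(index=False).encode())
    h.update(schedule_to_table(schedule).to_csv(index=False).encode())
    return h.hexdigest()[:16]
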