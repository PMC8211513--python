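"""Synthetic diagnosis corpora with known generative structure.

Real diagnosis corpora of this kind are typically private, so testing and
benchmarking run on generated ones. The generative model mirrors the
classifier's own assumptions on purpose: each record draws a disease from
a (possibly heavily skewed) prevalence vector, then emits each symptom of
that disease's profile by an independent Bernoulli coin (redrawing the
rare all-absent outcome), which makes the exact Bayes posterior available
in closed form as an oracle. Designated main symptoms are placed first in
the record, in profile order, with the remaining symptoms shuffled behind
them — encoding the convention that the first three recorded symptoms are
the most diagnostic.

Record length is whatever the Bernoulli emissions produce; there is no
separate length distribution, which would break the closed-form oracle.

Three ready-made study shapes are provided:

- :func:`make_spec` — the general corpus: ~100 diseases, Zipf-skewed
  prevalence, partial profile overlap;
- :func:`separable_spec` — every disease has exclusive high-emission main
  symptoms, so near-perfect ranking is achievable;
- :func:`imbalanced_spec` — 50:1 prevalence skew with profiles drawn from
  a small shared symptom pool, the class-imbalance stress case.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import MedicalRecord

__all__ = [
    "GenerativeSpec",
    "sample_corpus",
    "oracle_posterior",
    "make_spec",
    "separable_spec",
    "imbalanced_spec",
]


@dataclass
class GenerativeSpec:
    """Ground-truth generative parameters for a synthetic corpus."""

    diseases: tuple[str, ...]
    prevalence: tuple[float, ...]
    profiles: dict[str, dict[str, float]]
    main_symptoms: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if len(self.diseases) != len(self.prevalence):
            raise ValueError("one prevalence entry per disease required")
        if abs(sum(self.prevalence) - 1.0) > 1e-9:
            raise ValueError("prevalence must sum to 1")
        if any(p <= 0 for p in self.prevalence):
            raise ValueError("prevalence entries must be positive")
        for d in self.diseases:
            profile = self.profiles.get(d)
            if not profile:
                raise ValueError(f"disease {d!r} has no symptom profile")
            for s, p in profile.items():
                if not 0 < p <= 1:
                    raise ValueError(
                        f"emission probability for ({d!r}, {s!r}) must be in (0, 1]"
                    )
            for m in self.main_symptoms.get(d, ()):
                if m not in profile:
                    raise ValueError(
                        f"main symptom {m!r} of {d!r} not in its profile"
                    )

    @property
    def vocabulary(self) -> tuple[str, ...]:
        vocab: set[str] = set()
        for profile in self.profiles.values():
            vocab.update(profile)
        return tuple(sorted(vocab))

    def to_dict(self) -> dict:
        return {
            "diseases": list(self.diseases),
            "prevalence": list(self.prevalence),
            "profiles": {d: dict(p) for d, p in self.profiles.items()},
            "main_symptoms": {d: list(m) for d, m in self.main_symptoms.items()},
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GenerativeSpec":
        return cls(
            diseases=tuple(payload["diseases"]),
            prevalence=tuple(payload["prevalence"]),
            profiles={d: dict(p) for d, p in payload["profiles"].items()},
            main_symptoms={
                d: tuple(m) for d, m in payload["main_symptoms"].items()
            },
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GenerativeSpec":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def sample_corpus(
    spec: GenerativeSpec, n: int, seed: int
) -> list[MedicalRecord]:
    """Draw ``n`` records from the generative model, deterministically
    under a fixed seed.

    Per record: disease ~ prevalence; each profile symptom present with
    its emission probability (redraw if none came up); present main
    symptoms first in profile order, the rest in randomized order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prevalence = np.asarray(spec.prevalence, dtype=float)
    tables = []
    for d in spec.diseases:
        profile = spec.profiles[d]
        syms = np.array(list(profile), dtype=object)
        probs = np.array([profile[s] for s in syms], dtype=float)
        mains = spec.main_symptoms.get(d, ())
        tables.append((syms, probs, mains, set(mains)))
    disease_draws = rng.choice(len(spec.diseases), size=n, p=prevalence)
    records: list[MedicalRecord] = []
    for i, di in enumerate(disease_draws):
        syms, probs, mains, main_set = tables[di]
        while True:
            mask = rng.random(len(probs)) < probs
            if mask.any():
                break
        present = syms[mask]
        present_set = set(present)
        ordered = [m for m in mains if m in present_set]
        rest = np.array([s for s in present if s not in main_set], dtype=object)
        if len(rest):
            rest = rest[rng.permutation(len(rest))]
        ordered.extend(rest)
        records.append(
            MedicalRecord(spec.diseases[di], tuple(ordered), f"synt-{i}")
        )
    return records


def oracle_posterior(
    spec: GenerativeSpec, symptoms: Iterable[str]
) -> dict[str, float]:
    """Exact posterior P(d | the given symptoms present), absence of the
    other symptoms unobserved, by direct enumeration over diseases.

    The redraw-if-empty truncation of the sampler is ignored here; its
    effect is negligible for realistic profiles.
    """
    symptoms = list(symptoms)
    vocab = set(spec.vocabulary)
    for s in symptoms:
        if s not in vocab:
            raise KeyError(f"unknown symptom {s!r}")
    weights: dict[str, float] = {}
    for d, prior in zip(spec.diseases, spec.prevalence):
        profile = spec.profiles[d]
        w = prior
        for s in symptoms:
            w *= profile.get(s, 0.0)
        weights[d] = w
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no disease can emit all of these symptoms")
    return {d: w / total for d, w in weights.items()}


def _zipf_prevalence(n_diseases: int, skew: float) -> tuple[float, ...]:
    ranks = np.arange(1, n_diseases + 1, dtype=float)
    raw = ranks**-skew
    return tuple(raw / raw.sum())


def make_spec(
    n_diseases: int = 100,
    vocab_size: int = 300,
    skew: float = 1.0,
    overlap: float = 0.3,
    n_main: int = 3,
    n_secondary: tuple[int, int] = (4, 10),
    main_emission: tuple[float, float] = (0.6, 0.95),
    secondary_emission: tuple[float, float] = (0.05, 0.4),
    seed: int = 0,
) -> GenerativeSpec:
    """General study-shaped corpus spec: ~100 disease classes with
    Zipf-skewed prevalence, three high-emission main symptoms per disease,
    and partial profile overlap.

    ``overlap`` is the probability that a main-symptom slot reuses a main
    symptom of a previously built disease instead of claiming a fresh one;
    secondary symptoms are drawn from the full shared vocabulary, so
    overlap among them is automatic.
    """
    if n_diseases < 2 or vocab_size < n_diseases * n_main // 2:
        raise ValueError("vocabulary too small for the requested diseases")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must be in [0, 1]")
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_diseases - 1)))
    diseases = tuple(f"D{i:0{width}d}" for i in range(n_diseases))
    vocab = [f"s{i:04d}" for i in range(vocab_size)]
    profiles: dict[str, dict[str, float]] = {}
    main_symptoms: dict[str, tuple[str, ...]] = {}
    used_mains: list[str] = []
    fresh = list(rng.permutation(vocab))
    for d in diseases:
        mains: list[str] = []
        for _ in range(n_main):
            pick = None
            if used_mains and rng.random() < overlap:
                options = [m for m in used_mains if m not in mains]
                if options:
                    pick = options[int(rng.integers(len(options)))]
            if pick is None:
                while fresh and (fresh[-1] in mains or fresh[-1] in used_mains):
                    fresh.pop()
                if fresh:
                    pick = fresh.pop()
                else:  # vocabulary exhausted: fall back to reuse
                    options = [s for s in vocab if s not in mains]
                    pick = options[int(rng.integers(len(options)))]
            mains.append(pick)
            if pick not in used_mains:
                used_mains.append(pick)
        profile = {
            m: float(rng.uniform(*main_emission)) for m in mains
        }
        k_sec = int(rng.integers(n_secondary[0], n_secondary[1] + 1))
        pool = [s for s in vocab if s not in profile]
        for s in rng.choice(len(pool), size=min(k_sec, len(pool)), replace=False):
            profile[pool[int(s)]] = float(rng.uniform(*secondary_emission))
        profiles[d] = profile
        main_symptoms[d] = tuple(mains)
    return GenerativeSpec(
        diseases=diseases,
        prevalence=_zipf_prevalence(n_diseases, skew),
        profiles=profiles,
        main_symptoms=main_symptoms,
    )


def separable_spec(
    n_diseases: int = 20,
    n_exclusive_main: int = 2,
    main_emission: float = 0.9,
    n_shared: int = 30,
    n_background: int = 4,
    background_emission: float = 0.3,
    seed: int = 0,
) -> GenerativeSpec:
    """A separable corpus: each disease owns ``n_exclusive_main`` exclusive
    main symptoms with high emission, plus a few shared low-emission
    background symptoms. Uniform prevalence. Any sensible ranker should be
    near-perfect here."""
    rng = np.random.default_rng(seed)
    diseases = tuple(f"D{i:03d}" for i in range(n_diseases))
    shared = [f"bg{i:03d}" for i in range(n_shared)]
    profiles: dict[str, dict[str, float]] = {}
    main_symptoms: dict[str, tuple[str, ...]] = {}
    for i, d in enumerate(diseases):
        mains = tuple(f"m{i:03d}{chr(ord('a') + j)}" for j in range(n_exclusive_main))
        profile = {m: main_emission for m in mains}
        picks = rng.choice(n_shared, size=min(n_background, n_shared), replace=False)
        for p in picks:
            profile[shared[int(p)]] = background_emission
        profiles[d] = profile
        main_symptoms[d] = mains
    prevalence = tuple([1.0 / n_diseases] * n_diseases)
    return GenerativeSpec(diseases, prevalence, profiles, main_symptoms)


def imbalanced_spec(
    n_diseases: int = 20,
    prevalence_ratio: float = 50.0,
    pool_size: int = 60,
    n_main: int = 3,
    n_secondary: int = 5,
    main_emission: tuple[float, float] = (0.6, 0.9),
    secondary_emission: tuple[float, float] = (0.1, 0.4),
    seed: int = 0,
) -> GenerativeSpec:
    """Class-imbalance stress case: prevalence falls geometrically from the
    most to the least common disease (ratio ``prevalence_ratio``:1) and all
    profiles are drawn from one small shared symptom pool, so diseases
    overlap substantially."""
    if prevalence_ratio < 1:
        raise ValueError("prevalence_ratio must be >= 1")
    rng = np.random.default_rng(seed)
    diseases = tuple(f"D{i:03d}" for i in range(n_diseases))
    pool = [f"p{i:03d}" for i in range(pool_size)]
    profiles: dict[str, dict[str, float]] = {}
    main_symptoms: dict[str, tuple[str, ...]] = {}
    for d in diseases:
        picks = rng.choice(pool_size, size=n_main + n_secondary, replace=False)
        mains = tuple(pool[int(p)] for p in picks[:n_main])
        profile = {m: float(rng.uniform(*main_emission)) for m in mains}
        for p in picks[n_main:]:
            profile[pool[int(p)]] = float(rng.uniform(*secondary_emission))
        profiles[d] = profile
        main_symptoms[d] = mains
    exponents = np.linspace(0.0, 1.0, n_diseases)
    raw = prevalence_ratio ** (-exponents)
    prevalence = tuple(raw / raw.sum())
    return GenerativeSpec(diseases, prevalence, profiles, main_symptoms)
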