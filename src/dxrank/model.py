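"""Cooccurrence-count Naive Bayes variants for ranked differential diagnosis.

The scoring unit is the per-symptom *feature operator* — the likelihood
ratio P(symptom|disease)/P(symptom). A candidate disease's score is the
product of the operators of the input symptoms, optionally times a prior
term, optionally with the first three (main) symptoms up-weighted by a
coefficient w > 1 when they cooccur with the candidate. Pairs never seen
together fall back to a Laplace-smoothed conditional, so every candidate
keeps a small positive score instead of collapsing to zero.

Eight variants span the grid
{empirical prior, no prior, log form, equal probability} x {weighted,
unweighted}; see :func:`table_variants`. The equal-probability ("uniform")
variant replaces both the prior (1/|D|) and the symptom marginal by what a
class-balanced, oversampled corpus would induce — computed analytically as
the uniform mixture (1/|D|) * sum_d P(s|d), in exact rational arithmetic so
that on an already balanced corpus it coincides bitwise with the empirical
marginal.

All probabilities are record-level Bernoulli presence estimates: a symptom
counts once per record regardless of repetition.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus import MedicalRecord

__all__ = [
    "VariantConfig",
    "CooccurrenceModel",
    "Prediction",
    "fit",
    "table_variants",
    "oversample_balanced",
]

PRIOR_MODES = ("empirical", "none", "uniform")
FORMS = ("product", "log")


@dataclass(frozen=True)
class VariantConfig:
    """One cell of the variant grid, plus the scoring constants.

    Parameters
    ----------
    prior_mode:
        ``empirical`` — prior P(d) = N(d)/N; ``none`` — no prior term
        (the rate-of-change / likelihood-ratio form); ``uniform`` — the
        equal-probability variant: prior 1/|D| and uniform-mixture
        symptom marginal.
    form:
        ``product`` computes the score exactly as written; ``log`` sums
        logarithms instead, the numerically safe branch for long symptom
        lists where the product would underflow.
    weighted:
        whether the main-symptom weight coefficient is applied.
    weight:
        the coefficient w applied to a main symptom's operator when the
        symptom cooccurs with the candidate disease; meaningful for w > 1
        (w = 1 is allowed and makes weighting a no-op).
    n_main:
        how many leading input symptoms count as main symptoms.
    smoothing_alpha:
        the Laplace pseudo-count used for (disease, symptom) pairs with no
        cooccurrence: conditional = alpha / (N(d) + alpha * |vocabulary|).
    top_k:
        how many ranked diseases a prediction returns.
    """

    prior_mode: str = "empirical"
    form: str = "product"
    weighted: bool = False
    weight: float = 2.0
    n_main: int = 3
    smoothing_alpha: float = 1.0
    top_k: int = 3

    def __post_init__(self) -> None:
        if self.prior_mode not in PRIOR_MODES:
            raise ValueError(f"prior_mode must be one of {PRIOR_MODES}")
        if self.form not in FORMS:
            raise ValueError(f"form must be one of {FORMS}")
        if self.weight < 1:
            raise ValueError("weight coefficient must be >= 1")
        if self.smoothing_alpha <= 0:
            raise ValueError("smoothing_alpha must be > 0")
        if self.n_main < 0 or self.top_k < 1:
            raise ValueError("n_main must be >= 0 and top_k >= 1")

    @property
    def name(self) -> str:
        if self.form == "log":
            base = "log" if self.prior_mode == "empirical" else f"{self.prior_mode}-log"
        else:
            base = self.prior_mode
        return f"{base}:{'weighted' if self.weighted else 'unweighted'}"


def table_variants(
    weight: float = 2.0,
    n_main: int = 3,
    smoothing_alpha: float = 1.0,
    top_k: int = 3,
) -> dict[str, VariantConfig]:
    """The eight standard variants: {empirical prior, no prior, log form,
    equal probability} x {weighted, unweighted}, in grid order."""
    cells = (
        ("empirical", "product"),
        ("none", "product"),
        ("empirical", "log"),
        ("uniform", "product"),
    )
    grid: dict[str, VariantConfig] = {}
    for weighted in (True, False):
        for prior_mode, form in cells:
            cfg = VariantConfig(
                prior_mode=prior_mode,
                form=form,
                weighted=weighted,
                weight=weight,
                n_main=n_main,
                smoothing_alpha=smoothing_alpha,
                top_k=top_k,
            )
            grid[cfg.name] = cfg
    return grid


@dataclass(frozen=True)
class Prediction:
    """Ranked (disease, score) list, truncated to top_k, plus bookkeeping."""

    ranked: tuple[tuple[str, float], ...]
    candidates_considered: int
    status: str  # "ok" | "no_candidates"
    unknown_symptoms: tuple[str, ...] = ()


class CooccurrenceModel:
    """All the counts the scoring formulas need.

    ``n_records`` is the corpus size N; ``disease_counts[d]`` = N(d),
    records labeled d; ``symptom_counts[s]`` = N(s), records containing s;
    ``pair_counts[(d, s)]`` = N(d, s), records labeled d containing s.
    With single-label records, N(s) = sum_d N(d, s).
    """

    def __init__(
        self,
        n_records: int,
        disease_counts: Mapping[str, int],
        symptom_counts: Mapping[str, int],
        pair_counts: Mapping[tuple[str, str], int],
    ) -> None:
        if n_records <= 0:
            raise ValueError("model needs at least one record")
        self.n_records = int(n_records)
        self.disease_counts = dict(disease_counts)
        self.symptom_counts = dict(symptom_counts)
        self.pair_counts = dict(pair_counts)
        self._diseases = tuple(sorted(self.disease_counts))
        self._uniform_marg: dict[str, float] = {}
        self._by_symptom: dict[str, tuple[str, ...]] | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def fit(cls, records: Sequence[MedicalRecord]) -> "CooccurrenceModel":
        """Count records, diseases, symptoms and (disease, symptom) pairs.

        Presence/absence event model: a symptom counts once per record.
        """
        if not records:
            raise ValueError("cannot fit on an empty corpus")
        disease_counts: Counter = Counter()
        symptom_counts: Counter = Counter()
        pair_counts: Counter = Counter()
        for r in records:
            disease_counts[r.disease] += 1
            for s in set(r.symptoms):
                symptom_counts[s] += 1
                pair_counts[(r.disease, s)] += 1
        return cls(len(records), disease_counts, symptom_counts, pair_counts)

    # -- basic accessors ---------------------------------------------------

    @property
    def diseases(self) -> tuple[str, ...]:
        return self._diseases

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return tuple(sorted(self.symptom_counts))

    def _diseases_for(self, symptom: str) -> tuple[str, ...]:
        if self._by_symptom is None:
            by: dict[str, list[str]] = {}
            for (d, s), n in self.pair_counts.items():
                if n > 0:
                    by.setdefault(s, []).append(d)
            self._by_symptom = {s: tuple(sorted(ds)) for s, ds in by.items()}
        return self._by_symptom.get(symptom, ())

    # -- probability estimators --------------------------------------------

    def conditional_prob(self, symptom: str, disease: str) -> float:
        """Maximum-likelihood P(s|d) = N(d,s)/N(d), unsmoothed."""
        if disease not in self.disease_counts:
            raise KeyError(f"unknown disease {disease!r}")
        return self.pair_counts.get((disease, symptom), 0) / self.disease_counts[disease]

    def marginal_prob(self, symptom: str, prior_mode: str = "empirical") -> float:
        """Symptom marginal P(s).

        ``empirical`` / ``none`` use the corpus rate N(s)/N. ``uniform``
        uses the class-balanced mixture (1/|D|) * sum_d P(s|d) — the
        marginal an oversampled, class-balanced corpus would induce —
        evaluated exactly in rational arithmetic and rounded to float once.
        """
        if symptom not in self.symptom_counts:
            raise KeyError(f"unknown symptom {symptom!r}")
        if prior_mode != "uniform":
            return self.symptom_counts[symptom] / self.n_records
        cached = self._uniform_marg.get(symptom)
        if cached is None:
            acc = Fraction(0)
            for d in self._diseases:
                n_ds = self.pair_counts.get((d, symptom), 0)
                if n_ds:
                    acc += Fraction(n_ds, self.disease_counts[d])
            cached = float(acc / len(self._diseases))
            self._uniform_marg[symptom] = cached
        return cached

    def operator(self, symptom: str, disease: str, config: VariantConfig) -> float:
        """Feature operator for one (symptom, disease) pair.

        Cooccurring pair: P(s|d)/P(s). No cooccurrence: the
        Laplace-smoothed conditional alpha/(N(d) + alpha*|V|) over the same
        marginal — strictly positive and, for realistic counts, strictly
        smaller than any cooccurring operator on the same symptom. No
        main-symptom weighting here; that belongs to :meth:`score`.
        """
        marg = self.marginal_prob(symptom, config.prior_mode)
        n_ds = self.pair_counts.get((disease, symptom), 0)
        n_d = self.disease_counts.get(disease)
        if n_d is None:
            raise KeyError(f"unknown disease {disease!r}")
        if n_ds > 0:
            cond = n_ds / n_d
        else:
            alpha = config.smoothing_alpha
            cond = alpha / (n_d + alpha * len(self.symptom_counts))
        return cond / marg

    # -- scoring -----------------------------------------------------------

    def candidate_diseases(self, symptoms: Iterable[str]) -> set[str]:
        """Diseases cooccurring with at least one input symptom. Symptoms
        absent from the vocabulary are ignored."""
        out: set[str] = set()
        for s in symptoms:
            out.update(self._diseases_for(s))
        return out

    def _prior_term(self, disease: str, prior_mode: str) -> float:
        if prior_mode == "empirical":
            return self.disease_counts[disease] / self.n_records
        if prior_mode == "uniform":
            return 1.0 / len(self._diseases)
        return 1.0

    def score(
        self, symptoms: Sequence[str], disease: str, config: VariantConfig
    ) -> float:
        """Score one candidate on an ordered, deduplicated, in-vocabulary
        symptom list.

        Product form: prod_i(g_i * op_i) * prior, where g_i = w for a main
        symptom (position <= n_main) cooccurring with the candidate, else 1.
        Log form: the sum of logs of the same factors — identical ranking
        wherever the product does not underflow.
        """
        if disease not in self.disease_counts:
            raise KeyError(f"unknown disease {disease!r}")
        if not any(
            self.pair_counts.get((disease, s), 0) > 0 for s in symptoms
        ):
            raise ValueError(
                f"{disease!r} is not a candidate for this symptom list"
            )
        prior = self._prior_term(disease, config.prior_mode)
        if config.form == "product":
            acc = 1.0
            for i, s in enumerate(symptoms):
                factor = self.operator(s, disease, config)
                if (
                    config.weighted
                    and i < config.n_main
                    and self.pair_counts.get((disease, s), 0) > 0
                ):
                    factor = config.weight * factor
                acc *= factor
            return acc * prior
        acc = 0.0
        for i, s in enumerate(symptoms):
            factor = self.operator(s, disease, config)
            if (
                config.weighted
                and i < config.n_main
                and self.pair_counts.get((disease, s), 0) > 0
            ):
                factor = config.weight * factor
            acc += math.log(factor)
        return acc + math.log(prior)

    def predict_topk(
        self, symptoms: Sequence[str], config: VariantConfig | None = None
    ) -> Prediction:
        """Rank all candidate diseases for an ordered symptom list.

        Input symptoms are deduplicated (first occurrence kept) and split
        into in-vocabulary symptoms, which are scored, and unknown
        symptoms, which are reported. Ties are broken by lexicographic
        disease label for deterministic output.
        """
        config = config if config is not None else VariantConfig()
        seen: set[str] = set()
        known: list[str] = []
        unknown: list[str] = []
        for s in symptoms:
            if s in seen:
                continue
            seen.add(s)
            (known if s in self.symptom_counts else unknown).append(s)
        candidates = self.candidate_diseases(known)
        if not candidates:
            return Prediction((), 0, "no_candidates", tuple(unknown))
        scored = [(d, self.score(known, d, config)) for d in candidates]
        scored.sort(key=lambda pair: (-pair[1], pair[0]))
        return Prediction(
            tuple(scored[: config.top_k]), len(candidates), "ok", tuple(unknown)
        )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        pairs: dict[str, dict[str, int]] = {}
        for (d, s), n in sorted(self.pair_counts.items()):
            pairs.setdefault(d, {})[s] = n
        return {
            "n_records": self.n_records,
            "disease_counts": dict(sorted(self.disease_counts.items())),
            "symptom_counts": dict(sorted(self.symptom_counts.items())),
            "pair_counts": pairs,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CooccurrenceModel":
        pair_counts = {
            (d, s): int(n)
            for d, by_s in payload["pair_counts"].items()
            for s, n in by_s.items()
        }
        return cls(
            int(payload["n_records"]),
            {d: int(n) for d, n in payload["disease_counts"].items()},
            {s: int(n) for s, n in payload["symptom_counts"].items()},
            pair_counts,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CooccurrenceModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def fit(records: Sequence[MedicalRecord]) -> CooccurrenceModel:
    """Convenience wrapper around :meth:`CooccurrenceModel.fit`."""
    return CooccurrenceModel.fit(records)


def oversample_balanced(
    records: Sequence[MedicalRecord], limit: int = 1_000_000
) -> list[MedicalRecord]:
    """Replicate each class's records up to the least common multiple of
    the class counts, producing an exactly class-balanced corpus.

    This is the physical realization of the equal-probability variant; on
    the oversampled corpus the empirical symptom marginal equals the
    uniform-mixture marginal of the original corpus exactly, and the
    empirical prior becomes 1/|D|. Intended for consistency checks on
    small corpora — raises if the replicated corpus would exceed ``limit``
    records.
    """
    if not records:
        raise ValueError("cannot oversample an empty corpus")
    counts = Counter(r.disease for r in records)
    lcm = math.lcm(*counts.values())
    total = lcm * len(counts)
    if total > limit:
        raise ValueError(
            f"balanced corpus would need {total} records (limit {limit})"
        )
    out: list[MedicalRecord] = []
    for r in records:
        out.extend([r] * (lcm // counts[r.disease]))
    return out
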