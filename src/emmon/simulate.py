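"""Synthetic monitoring cohorts with difficulty-driven, correlated errors.

Real monitored classifiers and their monitor sub-models fail together on
hard cases: subtle true positives (small, low-contrast findings) and
mimicking true negatives (benign features resembling the finding, e.g.
calcification read as hemorrhage). The generator reproduces that structure
with the simplest adequate mechanism — a shared latent difficulty:

1. ``truth ~ Bernoulli(prevalence)`` per case;
2. a *phenotype* per case: positives are ``easy_pos`` or ``subtle_pos``
   (probability ``p_subtle``), negatives ``normal_neg`` or ``mimic_neg``
   (probability ``p_mimic``);
3. difficulty ``d ~ Beta(a, b)`` with phenotype-specific shapes;
4. the primary model and each of the K sub-models err *independently given
   d* with class-conditional probability ``clip(base + slope * d, 0, 1)``;
   an erring model outputs the flipped truth.

All cross-model error correlation therefore flows through ``d``
(conditional independence given difficulty); with every slope at 0 the
models err independently and the number of sub-models agreeing with a
correct primary prediction is exactly Binomial(K, 1 - eps).

Latent fields (phenotype, difficulty) are emitted to a separate table so
the main prediction table is indistinguishable from real monitoring input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import spearmanr

from .cohort import make_cohort
from .exceptions import SimConfigError

PHENOTYPES = ("easy_pos", "subtle_pos", "normal_neg", "mimic_neg")
CLASSES = ("positive", "negative")

ErrorParams = dict[str, tuple[float, float]]  # class -> (base, slope)


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic monitoring cohort.

    ``sub_error`` is either one class->(base, slope) mapping shared by all
    sub-models or a length-K sequence of such mappings.
    """

    n_cases: int
    prevalence: float
    k_submodels: int = 5
    p_subtle: float = 0.3
    p_mimic: float = 0.3
    difficulty_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "easy_pos": (1.0, 9.0),
            "subtle_pos": (6.0, 2.0),
            "normal_neg": (1.0, 9.0),
            "mimic_neg": (6.0, 2.0),
        }
    )
    primary_error: ErrorParams = field(
        default_factory=lambda: {"positive": (0.02, 0.4), "negative": (0.02, 0.4)}
    )
    sub_error: ErrorParams | Sequence[ErrorParams] = field(
        default_factory=lambda: {"positive": (0.03, 0.45), "negative": (0.03, 0.45)}
    )
    seed: int | None = None

    def sub_error_list(self) -> list[ErrorParams]:
        if isinstance(self.sub_error, dict):
            return [self.sub_error] * self.k_submodels
        return list(self.sub_error)

    def validate(self) -> "SimConfig":
        problems = []
        if self.n_cases < 1:
            problems.append("n_cases must be >= 1")
        if not (0 <= self.prevalence <= 1):
            problems.append("prevalence must be in [0, 1]")
        if self.k_submodels < 1:
            problems.append("k_submodels must be >= 1")
        for name, val in (("p_subtle", self.p_subtle), ("p_mimic", self.p_mimic)):
            if not (0 <= val <= 1):
                problems.append(f"{name} must be in [0, 1]")
        for ph in PHENOTYPES:
            ab = self.difficulty_params.get(ph)
            if ab is None or len(ab) != 2 or ab[0] <= 0 or ab[1] <= 0:
                problems.append(f"difficulty_params[{ph!r}] must be a positive Beta (a, b) pair")
        subs = self.sub_error_list()
        if not isinstance(self.sub_error, dict) and len(subs) != self.k_submodels:
            problems.append("sub_error list length must equal k_submodels")
        for label, em in [("primary_error", self.primary_error)] + [
            (f"sub_error[{i}]", em) for i, em in enumerate(subs)
        ]:
            for cls in CLASSES:
                bs = em.get(cls)
                if bs is None or len(bs) != 2 or not (0 <= bs[0] <= 1):
                    problems.append(f"{label}[{cls!r}] must be (base in [0,1], slope)")
        if problems:
            raise SimConfigError(problems)
        return self

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        doc = yaml.safe_load(open(path))

        def as_err(d):
            return {c: tuple(map(float, d[c])) for c in CLASSES}

        sub = doc.get("sub_error")
        if isinstance(sub, list):
            sub = [as_err(e) for e in sub]
        elif sub is not None:
            sub = as_err(sub)
        kwargs = {k: doc[k] for k in ("n_cases", "prevalence") if k in doc}
        for k in ("k_submodels", "p_subtle", "p_mimic", "seed"):
            if k in doc:
                kwargs[k] = doc[k]
        if "difficulty_params" in doc:
            kwargs["difficulty_params"] = {
                ph: tuple(map(float, ab)) for ph, ab in doc["difficulty_params"].items()
            }
        if "primary_error" in doc:
            kwargs["primary_error"] = as_err(doc["primary_error"])
        if sub is not None:
            kwargs["sub_error"] = sub
        return cls(**kwargs).validate()


def clinical_ich_preset(
    n_cases: int = 3000, prevalence: float = 0.45, seed: int | None = None
) -> SimConfig:
    """Frozen preset emulating a hemorrhage-detection monitoring cohort.

    At 45% prevalence with five sub-models this yields a four-cell
    agreement-by-correctness partition in the neighbourhood of roughly
    half full-agreement-correct, a quarter-plus partial-correct, a sixth
    partial-incorrect and a few percent full-agreement-incorrect. The
    parameter values are a fixture chosen by the implementers, not an
    estimate of any real model's error process.
    """
    return SimConfig(
        n_cases=n_cases,
        prevalence=prevalence,
        k_submodels=5,
        p_subtle=0.25,
        p_mimic=0.25,
        difficulty_params={
            "easy_pos": (1.0, 12.0),
            "subtle_pos": (4.0, 1.0),
            "normal_neg": (1.0, 12.0),
            "mimic_neg": (4.0, 1.0),
        },
        primary_error={"positive": (0.01, 0.75), "negative": (0.01, 0.75)},
        sub_error={"positive": (0.02, 0.75), "negative": (0.02, 0.75)},
        seed=seed,
    ).validate()


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def _error_prob(em: ErrorParams, truth: np.ndarray, d: np.ndarray) -> np.ndarray:
    bp, sp = em["positive"]
    bn, sn = em["negative"]
    return np.where(truth == 1, _clip01(bp + sp * d), _clip01(bn + sn * d))


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic cohort; returns (prediction table, latent table).

    The prediction table has the standard cohort schema (case_id, truth,
    primary, sub_1..sub_K); the latent table carries case_id, phenotype and
    difficulty. Output is fully determined by ``config`` (including its
    seed) — the draw order is fixed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_cases, config.k_submodels

    truth = (rng.random(n) < config.prevalence).astype(int)
    u_ph = rng.random(n)
    phenotype = np.where(
        truth == 1,
        np.where(u_ph < config.p_subtle, "subtle_pos", "easy_pos"),
        np.where(u_ph < config.p_mimic, "mimic_neg", "normal_neg"),
    )
    difficulty = np.empty(n)
    for ph in PHENOTYPES:  # fixed phenotype order keeps the draw sequence stable
        m = phenotype == ph
        if m.any():
            a, b = config.difficulty_params[ph]
            difficulty[m] = rng.beta(a, b, size=int(m.sum()))

    u_err = rng.random((n, k + 1))
    primary_err = u_err[:, 0] < _error_prob(config.primary_error, truth, difficulty)
    primary = np.where(primary_err, 1 - truth, truth)
    subs = np.empty((n, k), dtype=int)
    for j, em in enumerate(config.sub_error_list()):
        err = u_err[:, j + 1] < _error_prob(em, truth, difficulty)
        subs[:, j] = np.where(err, 1 - truth, truth)

    case_ids = [f"sim_{i:06d}" for i in range(n)]
    preds = make_cohort(primary=primary, subs=subs, truth=truth, case_ids=case_ids)
    latent = pd.DataFrame(
        {"case_id": case_ids, "phenotype": phenotype, "difficulty": difficulty}
    )
    return preds, latent


def agreement_difficulty_association(
    preds: pd.DataFrame, latent: pd.DataFrame
) -> float:
    """Spearman correlation between latent difficulty and agreement level.

    With positive error slopes, harder cases get lower agreement, so the
    correlation is negative. Returns NaN when agreement (or difficulty) is
    constant, where a rank correlation is undefined.
    """
    from .monitor import agreement_table

    agg = agreement_table(preds).merge(latent, on="case_id")
    if agg["agreement"].nunique() < 2 or agg["difficulty"].nunique() < 2:
        return float("nan")
    rho = spearmanr(agg["difficulty"], agg["agreement"]).statistic
    return float(rho)
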