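"""Threshold policies mapping agreement levels to confidence strata.

A policy assigns, separately for positive and negative primary predictions,
every attainable agreement level (in integer percent; K sub-models yield
levels ``round(100*j/K)`` for ``j = 0..K``) to one of three confidence
strata: ``decreased``, ``similar`` or ``increased``.

Two invariants are enforced on construction:

* totality — every attainable level of the policy's K maps to exactly one
  stratum, per sign;
* monotonicity — within a sign, confidence never drops as agreement rises
  (no ``decreased`` above a ``similar``, no ``similar`` above an
  ``increased``).

The shipped default (``default_policy``) encodes the clinically vetted
policy for K = 5 intracranial-hemorrhage monitoring: positive predictions
gain confidence only at 100% agreement and lose it at 0–40%; negative
predictions lose confidence only at 0% agreement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import round_half_away
from .exceptions import InvalidParameterError, PolicyMismatchError

SIGNS = ("positive", "negative")
STRATUM_RANK = {"decreased": 0, "similar": 1, "increased": 2}


def attainable_levels(k: int) -> list[int]:
    """Integer-percent agreement levels attainable with K sub-models."""
    if k < 1:
        raise InvalidParameterError("K must be >= 1")
    levels = [round_half_away(100 * j / k) for j in range(k + 1)]
    if len(set(levels)) != k + 1:
        raise InvalidParameterError(f"K={k} yields colliding integer-percent levels")
    return levels


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-sign mapping from agreement level (integer percent) to stratum."""

    positive: dict[int, str]
    negative: dict[int, str]
    k: int = field(default=5)

    def __post_init__(self):
        levels = attainable_levels(self.k)
        for sign in SIGNS:
            mapping = getattr(self, sign)
            if sorted(mapping) != levels:
                raise PolicyMismatchError(
                    f"{sign} mapping must cover exactly the levels {levels}, got {sorted(mapping)}"
                )
            for lvl, stratum in mapping.items():
                if stratum not in STRATUM_RANK:
                    raise InvalidParameterError(f"unknown stratum {stratum!r} at level {lvl}")
            ranks = [STRATUM_RANK[mapping[lvl]] for lvl in levels]
            if any(a > b for a, b in zip(ranks, ranks[1:])):
                raise PolicyMismatchError(
                    f"{sign} mapping is not monotone in agreement: {[mapping[l] for l in levels]}"
                )

    def stratum(self, level_percent: int, sign: str) -> str:
        if sign not in SIGNS:
            raise InvalidParameterError(f"sign must be one of {SIGNS}, got {sign!r}")
        mapping = getattr(self, sign)
        if level_percent not in mapping:
            raise PolicyMismatchError(
                f"agreement level {level_percent}% not covered by this K={self.k} policy"
            )
        return mapping[level_percent]

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "positive": {int(l): s for l, s in sorted(self.positive.items())},
            "negative": {int(l): s for l, s in sorted(self.negative.items())},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ThresholdPolicy":
        k = int(d.get("k", 5))
        return cls(
            positive={int(l): str(s) for l, s in d["positive"].items()},
            negative={int(l): str(s) for l, s in d["negative"].items()},
            k=k,
        )

    def save(self, path) -> None:
        path = Path(path)
        doc = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(doc, sort_keys=False))
        else:
            path.write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def load(cls, path) -> "ThresholdPolicy":
        path = Path(path)
        text = path.read_text()
        doc = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(doc)


def default_policy(k: int = 5) -> ThresholdPolicy:
    """The default K = 5 review policy.

    Positive primary predictions: 100% agreement → increased confidence,
    60–80% → similar, 0–40% → decreased. Negative primary predictions:
    100% → increased, 20–80% → similar, 0% → decreased.
    """
    if k != 5:
        raise InvalidParameterError("the default policy is defined for K = 5")
    return ThresholdPolicy(
        positive={0: "decreased", 20: "decreased", 40: "decreased",
                  60: "similar", 80: "similar", 100: "increased"},
        negative={0: "decreased", 20: "similar", 40: "similar",
                  60: "similar", 80: "similar", 100: "increased"},
        k=5,
    )
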