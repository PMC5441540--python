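"""Synthetic transcripts and cohorts with controllable connectedness structure.

No clinical data ship with the package; this module generates token
sequences and cohorts whose statistical structure matches what the
analysis assumes, so that every pipeline stage is testable end to end.

Transcripts come from a recurrence process: tokens are emitted one at a
time; with probability ``rho`` a step revisits an already-used word,
otherwise a fresh word from an unbounded vocabulary is emitted. Revisits
are recency-weighted by default (a geometric distribution over words
ordered most-recently-used first), which clusters recurrences locally the
way syntax clusters real speech. Under the word-shuffle surrogate null
this produces the clinically observed gradient: at ``rho`` near 0 a report
is loop-free and indistinguishable from its own shuffles (random-like,
the schizophrenia-like regime), while increasing ``rho`` grows LSC and
pushes LSCz many surrogate standard deviations away from 0 (structured,
the control-like regime). Note the deviation is *negative*: locally
clustered recurrences make smaller loops than the same words shuffled,
and it is the magnitude |LSCz| > 2 that marks structured speech here. A
``uniform`` revisit mode is available as a structureless control: its
orderings are nearly exchangeable, hence random-like at any rho.

Negative-symptom scores are generated *from the graph attributes* (not
from group labels), so the anchoring assumption of the Disorganization
Index — attributes explain negative-symptom variance — is true by
construction at a configurable effect size. Scores are clipped to the
PANSS negative subscale's feasible range [7, 49].

The generator is this module's own invention: it emulates connectedness
structure only, not natural-language semantics, morphology, or realistic
vocabulary frequency distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph import sequence_attributes
from .surrogate import DEFAULT_N_SURROGATES, make_surrogates, z_scores
from .transcript import REPORT_SUFFIX, Transcript

__all__ = [
    "SymptomModel",
    "GeneratorConfig",
    "DEFAULT_CONFIG",
    "generate_transcript",
    "generate_cohort",
]

GROUPS = ("schizophrenia_like", "bipolar_like", "control_like")
PANSS_NEGATIVE_RANGE = (7.0, 49.0)  # seven items, each scored 1-7


@dataclass(frozen=True)
class SymptomModel:
    """Linear map from connectedness attributes to a PANSS-negative-like total."""

    intercept: float = 32.0
    coefficients: dict[str, float] = field(
        default_factory=lambda: {"LSC": -0.8, "LSCz": 0.9, "LCC": 0.0}
    )
    noise_sd: float = 3.0
    #: report type whose attributes drive the score
    source_report: str = "image_negative"

    def mean_score(self, attributes: dict[str, float]) -> float:
        return self.intercept + sum(
            c * attributes[name] for name, c in self.coefficients.items()
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the recruited-cohort scale (11/10/21 subjects) with a
    recurrence gradient control_like >= bipolar_like >= schizophrenia_like
    chosen so that group random-like rates fall near the 64%/30%/5%
    clinical gradient. Per-subject rho is drawn uniformly from the group's
    range. Report lengths emulate 30-second reports (uniform 40-120
    tokens).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {
            "schizophrenia_like": 11, "bipolar_like": 10, "control_like": 21,
        }
    )
    tokens_min: int = 40
    tokens_max: int = 120
    rho_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "schizophrenia_like": (0.00, 0.04),
            "bipolar_like": (0.01, 0.08),
            "control_like": (0.08, 0.30),
        }
    )
    revisit_mode: str = "recency"  # "recency" or "uniform"
    recency_p: float = 0.5  # geometric weight over most-recent-first word ranks
    report_types: tuple[str, ...] = ("dream", "image_negative")
    symptom_model: SymptomModel = field(default_factory=SymptomModel)
    n_surrogates: int = DEFAULT_N_SURROGATES
    seed: int = 0

    def __post_init__(self) -> None:
        for g, (lo, hi) in self.rho_ranges.items():
            if not (0.0 <= lo <= hi < 1.0):
                raise ValueError(f"rho range for {g} must satisfy 0 <= lo <= hi < 1")
        if self.revisit_mode not in ("recency", "uniform"):
            raise ValueError("revisit_mode must be 'recency' or 'uniform'")
        if not (2 <= self.tokens_min <= self.tokens_max):
            raise ValueError("need 2 <= tokens_min <= tokens_max")


DEFAULT_CONFIG = GeneratorConfig()


def _generate_tokens(
    rng: np.random.Generator,
    length: int,
    rho: float,
    mode: str = "recency",
    recency_p: float = 0.5,
) -> list[str]:
    words = ["w0"]
    recency = [0]  # distinct word ids, most recent first
    nxt = 1
    for _ in range(length - 1):
        if nxt > 1 and rng.random() < rho:
            if mode == "uniform":
                r = int(rng.integers(0, len(recency)))
            else:
                r = int(rng.geometric(recency_p) - 1) % len(recency)
            w = recency.pop(r)
        else:
            w = nxt
            nxt += 1
        recency.insert(0, w)
        words.append(f"w{w}")
    return words


def generate_transcript(
    config: GeneratorConfig,
    group: str,
    rng: np.random.Generator,
    *,
    subject_id: str = "synthetic",
    report_type: str = "image_negative",
    rho: float | None = None,
) -> Transcript:
    """Draw one synthetic report for a subject of the given group.

    ``rho`` overrides the per-subject recurrence probability (otherwise a
    fresh draw from the group's range is used).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if rho is None:
        lo, hi = config.rho_ranges[group]
        rho = float(rng.uniform(lo, hi))
    length = int(rng.integers(config.tokens_min, config.tokens_max + 1))
    tokens = _generate_tokens(rng, length, rho, config.revisit_mode, config.recency_p)
    return Transcript(subject_id, report_type, tokens, duration_s=30.0)


def generate_cohort(
    config: GeneratorConfig = DEFAULT_CONFIG,
    seed: int | None = None,
    *,
    return_transcripts: bool = False,
):
    """Generate a full cohort table through the real analysis pipeline.

    Per subject and report type, a transcript is drawn, its connectedness
    attributes are computed with the production graph code, and its LSCz /
    LCCz are estimated against ``config.n_surrogates`` shuffled surrogates.
    Patients (schizophrenia_like, bipolar_like) receive a symptom score
    from ``config.symptom_model`` applied to the *true* attributes of the
    configured source report plus Gaussian noise, clipped to [7, 49];
    controls have no score (they are not clinical).

    Returns ``(cohort, ground_truth)`` — a per-subject DataFrame with
    attribute columns suffixed by report type (``LSC_negative``,
    ``LCC_dream``, ...) and a dict recording per-subject rho and the
    generating symptom model — plus the transcripts when requested.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    rows: list[dict] = []
    truth_rho: dict[str, float] = {}
    transcripts: list[Transcript] = []
    sm = config.symptom_model
    src_suffix = REPORT_SUFFIX[sm.source_report]
    for group in GROUPS:
        lo, hi = config.rho_ranges[group]
        for i in range(config.n_per_group.get(group, 0)):
            sid = f"{group[:3]}_{i:03d}"
            rho = float(rng.uniform(lo, hi))
            truth_rho[sid] = rho
            row: dict = {"subject_id": sid, "group": group, "rho": rho}
            for rt in config.report_types:
                t = generate_transcript(
                    config, group, rng, subject_id=sid, report_type=rt, rho=rho
                )
                attrs = sequence_attributes(t.tokens)
                dist = make_surrogates(t.tokens, config.n_surrogates, rng)
                scores = z_scores(attrs, dist)
                suf = REPORT_SUFFIX[rt]
                row.update({f"{k}_{suf}": v for k, v in attrs.as_dict().items()})
                row[f"LCCz_{suf}"] = scores.LCCz
                row[f"LSCz_{suf}"] = scores.LSCz
                row[f"random_like_{suf}"] = scores.random_like
                if return_transcripts:
                    transcripts.append(t)
            if group != "control_like":
                attr_values = {
                    name: row[f"{name}_{src_suffix}"] for name in sm.coefficients
                }
                score = sm.mean_score(attr_values) + rng.normal(0.0, sm.noise_sd)
                row["panss_negative"] = float(
                    np.clip(score, *PANSS_NEGATIVE_RANGE)
                )
            else:
                row["panss_negative"] = np.nan
            rows.append(row)
    cohort = pd.DataFrame(rows)
    ground_truth = {
        "seed": config.seed if seed is None else seed,
        "rho": truth_rho,
        "symptom_model": {
            "intercept": sm.intercept,
            "coefficients": {f"{k}_{src_suffix}": v for k, v in sm.coefficients.items()},
            "noise_sd": sm.noise_sd,
            "source_report": sm.source_report,
        },
        "revisit_mode": config.revisit_mode,
    }
    if return_transcripts:
        return cohort, ground_truth, transcripts
    return cohort, ground_truth
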