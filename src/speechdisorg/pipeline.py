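"""End-to-end orchestration: transcripts -> attributes -> surrogates ->
index -> statistics -> classification, with a reproducibility manifest.

The pipeline consumes a transcript TSV (subject_id, report_type, text) and
a per-subject metadata TSV (subject_id, group, optionally panss_negative
and confounders), and writes tidy CSV/JSON artifacts to an output
directory. Every stochastic stage derives its generator from the single
configured seed, so a manifest is sufficient to reproduce a run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import evaluate, median_split, naive_bayes_cv
from .graph import sequence_attributes
from .index import REFERENCE_INDICES, DisorganizationIndex, IndexModel
from .stats import bonferroni, kruskal_wallis, spearman, wilcoxon_ranksum
from .surrogate import make_surrogates, z_scores
from .transcript import REPORT_SUFFIX, Transcript, read_transcripts_tsv

__all__ = ["RunConfig", "run_pipeline", "attribute_table", "subject_table"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    transcripts_tsv: str | Path
    metadata_tsv: str | Path
    out_dir: str | Path
    report_types: tuple[str, ...] = ("dream", "image_negative")
    n_surrogates: int = 1000
    seed: int = 0
    #: name of a packaged reference index, a path to a model JSON, or "fit"
    index: str = "negative_dream"
    fit_candidates: tuple[str, ...] = ("LSC_negative", "LSCz_negative", "LCC_dream")
    symptom_column: str = "panss_negative"
    positive_group_prefix: str = "schiz"
    folds: int = 10


def attribute_table(
    transcripts: list[Transcript],
    n_surrogates: int,
    seed: int,
) -> pd.DataFrame:
    """Per-report connectedness attributes with surrogate z-scores.

    One row per report: E, LCC, LSC, word rate, normalized attributes,
    LCCz, LSCz, random_like. Surrogate seeds are derived per report from
    ``seed`` so row order does not perturb other rows' results.
    """
    rows = []
    for t in transcripts:
        attrs = sequence_attributes(t.tokens)
        digest = hashlib.sha256(
            f"{seed}:{t.subject_id}:{t.report_type}".encode()
        ).digest()
        sub_seed = int.from_bytes(digest[:4], "big") % (2**31)
        dist = make_surrogates(t.tokens, n_surrogates, sub_seed)
        sc = z_scores(attrs, dist)
        rows.append(
            {
                "subject_id": t.subject_id,
                "report_type": t.report_type,
                **attrs.as_dict(),
                "LCCz": sc.LCCz,
                "LSCz": sc.LSCz,
                "random_like": sc.random_like,
            }
        )
    return pd.DataFrame(rows)


def subject_table(attr_table: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Pivot per-report rows to one wide row per subject, joined to metadata.

    Attribute columns are suffixed with the report type's short name
    (``LSC_negative``, ``LCC_dream``, ...), matching how index models name
    their inputs.
    """
    value_cols = [
        c for c in attr_table.columns if c not in ("subject_id", "report_type")
    ]
    wides = []
    for rt, sub in attr_table.groupby("report_type"):
        suf = REPORT_SUFFIX[rt]
        renamed = sub.set_index("subject_id")[value_cols].rename(
            columns={c: f"{c}_{suf}" for c in value_cols}
        )
        wides.append(renamed)
    wide = pd.concat(wides, axis=1).reset_index()
    merged = metadata.merge(wide, on="subject_id", how="left", validate="1:1")
    return merged


def _index_scores(
    cohort: pd.DataFrame, cfg: RunConfig
) -> tuple[pd.Series, pd.Series, IndexModel]:
    """Index score per subject, with fallback to the negative-image-only
    reference index for subjects missing an attribute (e.g. no dream)."""
    if cfg.index == "fit":
        model = (
            DisorganizationIndex.from_cohort(
                cohort, list(cfg.fit_candidates), cfg.symptom_column,
                name="fitted", source_reports=cfg.report_types,
            )
            .fit()
            .to_model()
        )
    elif cfg.index in REFERENCE_INDICES:
        model = REFERENCE_INDICES[cfg.index]
    else:
        model = IndexModel.from_json(Path(cfg.index).read_text(encoding="utf-8"))
    fallback = REFERENCE_INDICES["negative"]
    scores = pd.Series(np.nan, index=cohort.index, dtype=float)
    used = pd.Series("", index=cohort.index, dtype=object)
    for i, row in cohort.iterrows():
        attrs = row.to_dict()
        try:
            scores[i] = model.score({k: v for k, v in attrs.items() if pd.notna(v)})
            used[i] = model.name
        except KeyError:
            try:
                scores[i] = fallback.score({k: v for k, v in attrs.items() if pd.notna(v)})
                used[i] = fallback.name
                logger.info(
                    "subject %s: missing attribute for index %r; fell back to "
                    "negative-image-only index", row["subject_id"], model.name,
                )
            except KeyError:
                logger.warning(
                    "subject %s: cannot evaluate any index", row["subject_id"]
                )
    return scores, used, model


def _group_stats(cohort: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Kruskal-Wallis across groups, schizophrenia-vs-rest rank-sum, and
    symptom Spearman for each attribute column, Bonferroni-thresholded."""
    attr_cols = [
        c for c in cohort.columns
        if any(c.startswith(p) for p in ("E_", "LCC_", "LSC_", "LCCz_", "LSCz_"))
        and cohort[c].dtype != object and not c.startswith("random_like")
    ]
    groups = list(cohort["group"].unique())
    is_pos = cohort["group"].str.startswith(cfg.positive_group_prefix)
    rows = []
    m = max(len(attr_cols), 1)
    alpha_corr = bonferroni(0.05, m)
    for col in attr_cols:
        vals = cohort[col]
        ok = vals.notna()
        try:
            kw = kruskal_wallis(*[vals[ok & (cohort["group"] == g)] for g in groups])
            rows.append(
                {"comparison": f"{col} across groups", "method": kw.method,
                 "statistic": kw.statistic, "p": kw.p_value,
                 "corrected_alpha": alpha_corr,
                 "significant": kw.p_value < alpha_corr}
            )
        except ValueError as exc:
            logger.warning("skipping Kruskal-Wallis on %s: %s", col, exc)
        try:
            rs = wilcoxon_ranksum(vals[ok & is_pos], vals[ok & ~is_pos])
            rows.append(
                {"comparison": f"{col} schizophrenia vs rest", "method": rs.method,
                 "statistic": rs.statistic, "p": rs.p_value,
                 "corrected_alpha": alpha_corr,
                 "significant": rs.p_value < alpha_corr}
            )
        except ValueError as exc:
            logger.warning("skipping rank-sum on %s: %s", col, exc)
        sym = cohort[cfg.symptom_column]
        use = ok & sym.notna()
        if use.sum() >= 3:
            try:
                sp = spearman(vals[use], sym[use])
                rows.append(
                    {"comparison": f"{col} vs {cfg.symptom_column}", "method": sp.method,
                     "statistic": sp.statistic, "p": sp.p_value,
                     "corrected_alpha": alpha_corr,
                     "significant": sp.p_value < alpha_corr}
                )
            except ValueError as exc:
                logger.warning("skipping Spearman on %s: %s", col, exc)
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the full analysis; returns a manifest dict (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    transcripts = [
        t for t in read_transcripts_tsv(cfg.transcripts_tsv)
        if t.report_type in cfg.report_types
    ]
    if not transcripts:
        raise ValueError("no transcripts of the requested report types found")
    metadata = pd.read_csv(cfg.metadata_tsv, sep="\t")
    required = {"subject_id", "group"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    if cfg.symptom_column not in metadata.columns:
        metadata[cfg.symptom_column] = np.nan
    bad = metadata["subject_id"].isna() | metadata["group"].isna()
    if bad.any():
        raise ValueError(
            f"corrupt metadata rows (missing subject_id/group): "
            f"lines {[int(i) + 2 for i in metadata.index[bad]]}"
        )

    attrs = attribute_table(transcripts, cfg.n_surrogates, cfg.seed)
    attrs.to_csv(out / "attributes.csv", index=False)

    cohort = subject_table(attrs, metadata)
    scores, used, model = _index_scores(cohort, cfg)
    cohort["disorganization_index"] = scores
    cohort["index_model_used"] = used
    cohort.to_csv(out / "cohort.csv", index=False)
    (out / "index_model.json").write_text(model.to_json(), encoding="utf-8")

    stats_df = _group_stats(cohort, cfg)
    stats_df.to_csv(out / "statistics.csv", index=False)

    classification: dict[str, dict] = {}
    have_index = cohort["disorganization_index"].notna()
    y_diag = cohort["group"].str.startswith(cfg.positive_group_prefix).astype(int)
    if have_index.sum() >= cfg.folds and y_diag[have_index].nunique() == 2:
        rep = naive_bayes_cv(
            cohort.loc[have_index, "disorganization_index"].to_numpy(),
            y_diag[have_index].to_numpy(),
            folds=cfg.folds,
            seed=cfg.seed,
        )
        classification["diagnosis"] = rep.as_dict()
    sym = cohort[cfg.symptom_column]
    patients = sym.notna() & have_index
    if patients.sum() >= 4:
        split = median_split(sym[patients])
        y_sev = split.as_binary()
        if len(set(y_sev)) == 2:
            rep = naive_bayes_cv(
                cohort.loc[patients, "disorganization_index"].to_numpy(),
                y_sev, folds=cfg.folds, seed=cfg.seed,
            )
            d = rep.as_dict()
            d["cutoff"] = split.cutoff
            classification["severity"] = d
    (out / "classification.json").write_text(
        json.dumps(classification, indent=2), encoding="utf-8"
    )

    cfg_dict = {k: (str(v) if isinstance(v, Path) else v) for k, v in vars(cfg).items()}
    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "n_surrogates": cfg.n_surrogates,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_transcripts": len(transcripts),
        "n_subjects": int(len(cohort)),
        "index_model": model.name,
        "artifacts": [
            "attributes.csv", "cohort.csv", "index_model.json",
            "statistics.csv", "classification.json", "manifest.json",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
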