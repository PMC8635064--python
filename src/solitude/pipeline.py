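"""End-to-end orchestration: transcripts -> localization -> features ->
feature table -> Gini ranking -> LOOCV evaluation -> report.

`TranscriptFeaturizer` is the sklearn-style front end (a stateless
transformer: transcripts in, a participant x feature DataFrame out); the
rest of the pipeline composes it with the modeling layer.  All artifacts
embed the config hash and seed so runs from different configurations never
overwrite each other silently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import localization as loc
from . import lexicons
from .features import linguistic_feature_vector
from .modeling import (BinaryTarget, FeatureTable, ModelSpec,
                       assemble_feature_table, binarize_target, gini_rank,
                       incremental_selection)
from .social import build_social_profile
from .tagger import default_tagger
from .transcripts import Transcript, read_transcript_dir

logger = logging.getLogger("solitude")

_MODES = ("phone", "email", "social_media", "in_person", "video")

#: Scale columns of the scores table and their binarization defaults.
TARGET_RULES = {
    "ucla": ("fixed", 40.0),
    "ess_e": ("median", None),
    "ess_i": ("median", None),
    "ess_ni": ("median", None),
    "ssi": ("median", None),
}


class TranscriptFeaturizer(BaseEstimator, TransformerMixin):
    """Transform parsed transcripts into the participant x feature table.

    For each transcript the six template questions are located by TF-IDF
    retrieval; linguistic features come from the relationship-section
    responses, relationship/communication features from the Q1/Q3/Q4
    responses, pronoun densities from the participant's speech in the whole
    interview and in the relationship section.

    Parameters
    ----------
    template_path, sentiment_path, filler_path, relationship_path,
    communication_path : optional str
        Overrides for the packaged lexicon/template files.
    pronoun_scope : str
        Scope of the pronoun-density features used for modeling:
        ``"transcript"`` (default) or ``"section"``.  Both scopes are always
        emitted; this merely names the default.
    """

    def __init__(self, template_path: Optional[str] = None,
                 sentiment_path: Optional[str] = None,
                 filler_path: Optional[str] = None,
                 relationship_path: Optional[str] = None,
                 communication_path: Optional[str] = None,
                 pronoun_scope: str = "transcript"):
        self.template_path = template_path
        self.sentiment_path = sentiment_path
        self.filler_path = filler_path
        self.relationship_path = relationship_path
        self.communication_path = communication_path
        self.pronoun_scope = pronoun_scope

    def fit(self, X=None, y=None) -> "TranscriptFeaturizer":
        self.templates_ = loc.load_templates(self.template_path)
        self.sentiment_lexicon_ = lexicons.load_sentiment_lexicon(
            self.sentiment_path)
        self.filler_lexicon_ = lexicons.load_filler_lexicon(self.filler_path)
        self.relationship_lexicon_ = lexicons.load_relationship_lexicon(
            self.relationship_path)
        freq, mode = lexicons.load_communication_lexicon(
            self.communication_path)
        self.frequency_lexicon_, self.mode_lexicon_ = freq, mode
        self.tagger_ = default_tagger()
        self.rel_categories_ = sorted(set(
            self.relationship_lexicon_.values()))
        return self

    def _ensure_fitted(self) -> None:
        if not hasattr(self, "templates_"):
            self.fit()

    def featurize_one(self, transcript: Transcript) -> Dict[str, float]:
        """Feature row for one transcript (also records localization
        metadata under ``_loc_*`` keys, excluded from modeling)."""
        self._ensure_fitted()
        located = loc.localize_all(transcript, self.templates_)
        responses = [located[t.label].response_text for t in self.templates_]
        row: Dict[str, float] = {}
        row.update(linguistic_feature_vector(
            responses, self.tagger_, self.sentiment_lexicon_,
            self.filler_lexicon_))
        profile = build_social_profile(
            whole_transcript_text=transcript.participant_text(),
            section_text=" ".join(responses),
            q1_response=located["Q1"].response_text,
            q3_response=located["Q3"].response_text,
            q4_response=located["Q4"].response_text,
            relationship_lexicon=self.relationship_lexicon_,
            frequency_lexicon=self.frequency_lexicon_,
            mode_lexicon=self.mode_lexicon_)
        for category in self.rel_categories_:
            row[f"social_important_{category}"] = float(
                profile.important_counts.get(category, 0))
        row["social_important_total"] = float(profile.important_total)
        row["social_understood_total"] = float(profile.understood_total)
        row["social_none_understood"] = float(profile.none_understood)
        row["social_comm_frequency_per_month"] = (
            float("nan") if profile.comm_frequency_per_month is None
            else float(profile.comm_frequency_per_month))
        for mode in _MODES:
            row[f"social_mode_{mode}"] = float(mode in profile.modes)
        for key, value in profile.pronoun_density.items():
            scope, cls = key.split("_", 1)
            row[f"pron_{cls}_{scope}"] = value
        for label, located_response in located.items():
            row[f"_loc_{label}_turn"] = float(
                located_response.matched_turn_index)
            row[f"_loc_{label}_similarity"] = located_response.similarity
        return row

    def transform(self, X: Sequence[Transcript]) -> pd.DataFrame:
        self._ensure_fitted()
        rows = {}
        for transcript in X:
            try:
                rows[transcript.participant_id] = self.featurize_one(
                    transcript)
            except Exception as exc:
                raise RuntimeError(
                    "feature extraction failed for participant "
                    f"{transcript.participant_id!r}") from exc
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "participant_id"
        return frame


def modeling_columns(frame: pd.DataFrame) -> List[str]:
    """Feature columns used for modeling (localization metadata excluded)."""
    return [c for c in frame.columns if not c.startswith("_loc_")]


def demographics_frame(scores: pd.DataFrame) -> pd.DataFrame:
    """Numeric sociodemographic features from the scores table."""
    demo = pd.DataFrame(index=scores.index)
    demo["age"] = pd.to_numeric(scores["age"])
    demo["education"] = pd.to_numeric(scores["education"])
    demo["gender_female"] = (scores["gender"] == "women").astype(float)
    demo["race_caucasian"] = (scores["race"] == "caucasian").astype(float)
    demo["marital_not_single"] = (
        scores["marital"] == "not_single").astype(float)
    return demo


@dataclass
class PipelineConfig:
    transcripts_dir: str
    scores_csv: str
    output_dir: str
    target: str = "ucla"
    rule: Optional[str] = None       # default per TARGET_RULES
    cutoff: Optional[float] = None
    model_family: str = "ann_logistic"
    hyperparameters: Dict = field(default_factory=dict)
    k_max: int = 10
    pronoun_scope: str = "transcript"
    seed: int = 0
    template_path: Optional[str] = None
    sentiment_path: Optional[str] = None
    filler_path: Optional[str] = None
    relationship_path: Optional[str] = None
    communication_path: Optional[str] = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.transcripts_dir).is_dir():
            raise FileNotFoundError(
                f"transcripts dir not found: {self.transcripts_dir}")
        if not Path(self.scores_csv).is_file():
            raise FileNotFoundError(
                f"scores table not found: {self.scores_csv}")
        for path in (self.template_path, self.sentiment_path,
                     self.filler_path, self.relationship_path,
                     self.communication_path):
            if path is not None and not Path(path).is_file():
                raise FileNotFoundError(f"lexicon file not found: {path}")
        if self.target not in TARGET_RULES:
            raise ValueError(f"unknown target {self.target!r}")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def build_feature_table(
    frame: pd.DataFrame, scores: pd.DataFrame
) -> FeatureTable:
    """Join extracted features with demographics and scale scores."""
    features = frame[modeling_columns(frame)]
    demo = demographics_frame(scores)
    score_cols = [c for c in ("ucla", "ess_e", "ess_i", "ess_ni", "ssi")
                  if c in scores.columns]
    return assemble_feature_table(features, demo,
                                  scores[score_cols].apply(pd.to_numeric))


def prepare_target(
    table: FeatureTable, target: str,
    rule: Optional[str] = None, cutoff: Optional[float] = None,
):
    """Binarize one scale score, dropping participants missing that score."""
    default_rule, default_cut = TARGET_RULES[target]
    rule = rule or default_rule
    cutoff = cutoff if cutoff is not None else default_cut
    scores = pd.to_numeric(table.targets[target])
    keep = scores.notna()
    target_obj = binarize_target(scores[keep].to_numpy(), rule,
                                 cutoff=cutoff, name=target)
    subtable = FeatureTable(features=table.features.loc[keep],
                            targets=table.targets.loc[keep])
    return subtable, target_obj


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute the full stage sequence and write the run artifacts.

    Emits ``features.csv``, ``ranked_features.csv`` and ``metrics.json``
    under ``<output_dir>/run-<config hash>/``; returns the report dict.
    Idempotent given identical inputs.
    """
    config.validate()
    run_hash = config.config_hash()
    out = Path(config.output_dir) / f"run-{run_hash}"
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(out / "run.log")
    logger.addHandler(handler)
    try:
        logger.info("run %s: extracting features", run_hash)
        transcripts = list(read_transcript_dir(config.transcripts_dir))
        if not transcripts:
            raise FileNotFoundError(
                f"no transcripts in {config.transcripts_dir}")
        featurizer = TranscriptFeaturizer(
            template_path=config.template_path,
            sentiment_path=config.sentiment_path,
            filler_path=config.filler_path,
            relationship_path=config.relationship_path,
            communication_path=config.communication_path,
            pronoun_scope=config.pronoun_scope).fit()
        frame = featurizer.transform(transcripts)
        frame.to_csv(out / "features.csv")

        scores = pd.read_csv(config.scores_csv, index_col="participant_id")
        table = build_feature_table(frame, scores)
        subtable, target = prepare_target(table, config.target,
                                          config.rule, config.cutoff)
        logger.info("run %s: target %s cutoff %.3f (n=%d)", run_hash,
                    target.name, target.cutoff_value, len(target.labels))

        ranked = gini_rank(subtable, target)
        ranked.to_csv(out / "ranked_features.csv", index=False)

        spec = ModelSpec(family=config.model_family,
                         hyperparameters=dict(config.hyperparameters),
                         seed=config.seed)
        k_max = min(config.k_max, len(subtable.feature_names))
        selection = incremental_selection(
            subtable, target, spec, ranked["feature"].tolist(), k_max)
        result = selection.best_result
        report: Dict[str, object] = {
            "config_hash": run_hash,
            "seed": config.seed,
            "target": target.name,
            "rule": target.rule,
            "cutoff_value": target.cutoff_value,
            "n_participants": int(len(target.labels)),
            "model_family": spec.family,
            "selected_k": selection.best_k,
            "selected_features": selection.best_subset,
            "auc_curve": [[k, auc] for k, auc in selection.curve],
            "confusion": result.confusion,
            "sensitivity": result.sensitivity,
            "specificity": result.specificity,
            "f1_weighted": result.f1_weighted,
            "auc": result.auc,
            "imputation_log": table.imputation_log,
            "dropped_ids": table.dropped_ids,
        }
        with open(out / "metrics.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2)
        logger.info("run %s: AUC=%.3f F1=%.3f (k=%d)", run_hash,
                    result.auc, result.f1_weighted, selection.best_k)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
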