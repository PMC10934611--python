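"""End-to-end orchestration: event logs -> images -> features -> screening.

The stages mirror the system's architecture: ingest and noise-filter sensor
logs, segment locomotion episodes, encode each as an annotated trajectory
image, extract connected-region and visual-word features, evaluate the
per-episode classifier with leave-one-person-out cross-validation, and
aggregate episode predictions into a per-person diagnosis.  Everything is
callable as a library; the command-line interface is a thin shell over the
functions here.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assessment, features, movement, sensing_io
from .config import RunConfig

logger = logging.getLogger(__name__)


@dataclass
class Episode:
    """One encoded locomotion episode ready for feature extraction."""

    subject_id: str
    label: str
    index: int
    trajectory: movement.Trajectory
    image: movement.TrajectoryImage


def load_manifest(path) -> dict[str, str]:
    """subject_id -> label from a cohort manifest CSV."""
    df = pd.read_csv(path)
    return dict(zip(df["subject_id"].astype(str), df["label"].astype(str)))


def ingest_subject(
    events_path,
    table: sensing_io.SensorPositionTable,
    subject_id: str,
    label: str = "unknown",
    v_max: float = 15.0,
    d_max: float = 5.0,
) -> sensing_io.PositionHistory:
    """Parse one subject's event log into a noise-filtered position history."""
    stream = sensing_io.parse_event_stream(events_path)
    history = sensing_io.to_position_records(
        stream, table, subject_id=subject_id, label=label
    )
    return sensing_io.noise_filter(history, v_max=v_max, d_max=d_max)


def encode_episodes(
    history: sensing_io.PositionHistory,
    canvas: movement.CanvasSpec,
    layout_centroid: tuple[float, float],
    cfg: RunConfig,
    palette: movement.Palette | None = None,
) -> list[Episode]:
    """Segment a history and render every retained episode."""
    mv = cfg.movement
    episodes = []
    trajectories = movement.segment_trajectories(history, ts=mv.ts)
    for i, traj in enumerate(trajectories):
        movement.derive_kinematics(traj)
        interactions = [r for r in traj.records if r.category != "motion"]
        img = movement.encode_trajectory_image(
            traj,
            canvas,
            palette=palette,
            layout_centroid=layout_centroid,
            interactions=interactions,
            dwell_min=mv.dwell_min,
            theta_min=mv.theta_min,
            turn_min=mv.turn_min,
            center_tol=mv.center_tol,
        )
        episodes.append(
            Episode(
                subject_id=history.subject_id,
                label=history.label,
                index=i,
                trajectory=traj,
                image=img,
            )
        )
    return episodes


def build_episodes(cfg: RunConfig) -> list[Episode]:
    """Ingest every subject listed in the manifest and encode all episodes."""
    table = sensing_io.load_position_table(cfg.position_table)
    labels = load_manifest(cfg.manifest) if cfg.manifest else {}
    canvas = movement.CanvasSpec.fit(
        table, width_px=cfg.movement.canvas_width, height_px=cfg.movement.canvas_height
    )
    centroid = table.centroid()
    events_dir = Path(cfg.events_dir)
    episodes: list[Episode] = []
    for path in sorted(events_dir.glob("*.txt")):
        subject = path.stem
        history = ingest_subject(
            path,
            table,
            subject_id=subject,
            label=labels.get(subject, "unknown"),
            v_max=cfg.movement.v_max,
            d_max=cfg.movement.d_max,
        )
        episodes.extend(encode_episodes(history, canvas, centroid, cfg))
    logger.info("encoded %d episodes from %s", len(episodes), events_dir)
    return episodes


class EpisodeFeaturizer:
    """Caches per-episode CRF blocks and keypoint descriptors.

    Keypoint detection and the connected-region features do not depend on
    the visual vocabulary, so they are computed once; only the k-means
    vocabulary (and therefore the histogram columns) is refit per
    cross-validation fold from training-subject descriptors.
    """

    def __init__(self, episodes: list[Episode], K: int = 50, seed: int = 0, norm: str = "l2"):
        self.episodes = episodes
        self.K = K
        self.seed = seed
        self.norm = norm
        self.crf = np.array(
            [
                features.region_feature_vector(
                    movement.to_binary(movement.to_grayscale(ep.image)),
                    movement.to_grayscale(ep.image),
                )
                for ep in episodes
            ]
        )
        self.descriptors = [features.extract_descriptors(ep.image.rgb) for ep in episodes]

    def _histograms(self, vocab: features.VisualVocabulary) -> np.ndarray:
        return np.array(
            [
                features.encode_bovw(None, vocab, descriptors=d, norm=self.norm)
                for d in self.descriptors
            ]
        )

    def feature_matrix(self, train_mask: np.ndarray | None = None) -> np.ndarray:
        """CRF + BoVW features for all episodes.

        With ``train_mask`` given, the vocabulary is built from training
        episodes only (the leakage-free mode used inside LOPO folds).
        """
        if train_mask is None:
            pool = self.descriptors
        else:
            pool = [d for d, m in zip(self.descriptors, train_mask) if m]
        vocab = features.build_vocabulary(None, K=self.K, seed=self.seed, descriptors=pool)
        return np.hstack([self.crf, self._histograms(vocab)])

    def dataset(self, train_mask: np.ndarray | None = None) -> assessment.LabeledDataset:
        return assessment.LabeledDataset(
            X=self.feature_matrix(train_mask),
            y=np.array([ep.label for ep in self.episodes]),
            subjects=np.array([ep.subject_id for ep in self.episodes]),
        )


def evaluate_cohort(
    episodes: list[Episode], cfg: RunConfig, use_smote: bool | None = None
) -> dict:
    """LOPO evaluation plus long-term diagnosis for an encoded cohort.

    Returns a dict with short-term and long-term metric reports, the
    per-episode prediction frame and the per-subject diagnosis frame.
    """
    feat = EpisodeFeaturizer(episodes, K=cfg.features.K, seed=cfg.seed, norm=cfg.features.normalization)
    return evaluate_featurized(feat, cfg, use_smote=use_smote)


def evaluate_featurized(
    feat: EpisodeFeaturizer, cfg: RunConfig, use_smote: bool | None = None
) -> dict:
    smote = cfg.model.use_smote if use_smote is None else use_smote
    spec = assessment.ModelSpec(kind=cfg.model.kind, seed=cfg.seed)
    dataset = assessment.LabeledDataset(
        X=feat.crf,  # placeholder; featurizer supplies the real matrix per fold
        y=np.array([ep.label for ep in feat.episodes]),
        subjects=np.array([ep.subject_id for ep in feat.episodes]),
    )
    featurizer = feat.feature_matrix if cfg.model.refit_vocab_per_fold else None
    if featurizer is None:
        dataset = feat.dataset()
    # the histogram block is already unit-normalised; standardise CRF only
    scale_head = len(features.CRF_FIELDS) if cfg.features.normalization != "none" else None
    short_report, pred_df = assessment.lopo_evaluate(
        dataset,
        spec,
        use_smote=smote,
        smote_k=cfg.model.smote_k,
        featurizer=featurizer,
        scale_head=scale_head,
    )
    long_report, diag_df = assessment.long_term_evaluate(pred_df)
    return {
        "short_term": short_report,
        "long_term": long_report,
        "predictions": pred_df,
        "diagnoses": diag_df,
    }


def run_pipeline(cfg: RunConfig, write_images: bool = False) -> dict:
    """Execute every stage and write artifacts under ``cfg.out_dir``.

    Artifacts: per-episode PNGs and JSON sidecars (optional), the feature
    matrix CSV, metrics JSON (with a provenance stamp), per-episode
    prediction CSV and per-subject diagnosis CSV.  Re-running with the same
    configuration and seed reproduces identical CSV/JSON outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    episodes = build_episodes(cfg)
    if not episodes:
        raise RuntimeError("ingestion produced no locomotion episodes")
    logger.info("stage segment: %d episodes", len(episodes))

    if write_images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for ep in episodes:
            stem = f"{ep.subject_id}_{ep.index:04d}"
            movement.save_episode_png(ep.image, img_dir / f"{stem}.png")
            movement.save_episode_sidecar(ep.trajectory, ep.index, img_dir / f"{stem}.json")

    feat = EpisodeFeaturizer(
        episodes, K=cfg.features.K, seed=cfg.seed, norm=cfg.features.normalization
    )
    vocab = features.build_vocabulary(
        None, K=cfg.features.K, seed=cfg.seed, descriptors=feat.descriptors
    )
    vocab.save(out / "vocabulary.json")
    vectors = [
        features.assemble_feature_vector(
            feat.crf[i],
            features.encode_bovw(
                None, vocab, descriptors=feat.descriptors[i], norm=cfg.features.normalization
            ),
            ep.subject_id,
            ep.label,
        )
        for i, ep in enumerate(feat.episodes)
    ]
    features.feature_frame(vectors).to_csv(out / "features.csv", index=False)
    logger.info("stage features: wrote %s", out / "features.csv")

    results = evaluate_featurized(feat, cfg)
    provenance = {"config_digest": cfg.digest(), "seed": cfg.seed, "version": _version()}
    metrics = {
        "provenance": provenance,
        "n_episodes": len(episodes),
        "n_subjects": int(len(set(ep.subject_id for ep in episodes))),
        "short_term": results["short_term"].to_dict(),
        "long_term": results["long_term"].to_dict(),
    }
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    results["predictions"].to_csv(out / "predictions.csv", index=False)
    results["diagnoses"].to_csv(out / "diagnoses.csv", index=False)
    logger.info(
        "stage evaluate: short-term macro-F1 %.4f, long-term macro-F1 %.4f",
        results["short_term"].macro_f1,
        results["long_term"].macro_f1,
    )
    return metrics


def _version() -> str:
    from . import __version__

    return __version__
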