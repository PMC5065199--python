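"""End-to-end study orchestration: simulate, extract, analyze, report.

``run_study`` reproduces the study design on synthetic phantoms: for each
lesion it builds a noise-free phantom, emulates the three reconstruction
variants from one shared noise realization, simulates reader segmentations
(reader 1 twice, reader 2 once, all on the FBP image), propagates each ROI
unchanged across the variants, and extracts the 15 features — nine feature
datasets per lesion.  It then runs the algorithm-comparison ladder per
reader and the CV-based variability analysis, and renders the three result
tables (feature values per measurement, algorithm comparisons, CVs by
source with robustness categories).

All randomness derives from a single study seed; reruns from the same
configuration are byte-identical.  Every output embeds the configuration
hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats as vstats
from .core import (
    FEATURE_NAMES,
    SHAPE_FEATURE_NAMES,
    FeatureVector,
    ImageVolume,
    MeasurementRecord,
    RoiMask,
    propagate_roi,
)
from .firstorder import firstorder_features, masked_intensities
from .glcm import glcm_features_from_roi
from .shape import shape_features
from .synthetic import (
    ReaderSpec,
    ReconSpec,
    sample_phantom_spec,
    generate_phantom,
    simulate_reader,
    simulate_reconstructions,
)

__all__ = [
    "StudyConfig",
    "StudyResult",
    "extract_features",
    "simulate_study_records",
    "analyze_records",
    "run_study",
    "records_to_frame",
    "frame_to_records",
]

RECORD_COLUMNS = ("lesion_id", "reader_id", "session", "algorithm_label")

#: CV comparisons performed in one run (paper family of four: 0.05/4 ~ 0.013).
CV_COMPARISON_PAIRS = (
    ("intra_reader", "inter_reader"),
    ("inter_reader", "recon_FBP_S3"),
    ("inter_reader", "recon_FBP_S5"),
    ("inter_reader", "recon_S3_S5"),
)


@dataclass
class StudyConfig:
    """Fully serializable configuration of one simulated study run."""

    # cohort / phantom geometry
    n_lesions: int = 42
    seed: int = 0
    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing: tuple[float, float, float] = (0.68, 0.68, 1.00)
    size_mean_mm: float = 22.6
    size_sd_mm: float = 8.5
    size_range_mm: tuple[float, float] = (10.0, 41.7)
    # reconstruction emulation
    noise_sd_fbp: float = 60.0
    noise_correlation_length: float = 0.5
    r_s3: float = 0.60
    r_s5: float = 0.35
    # readers
    n_readers: int = 2
    intra_jitter_mm: float = 0.3
    inter_jitter_mm: float = 0.8
    # feature parameters
    bins: int = 256
    firstorder_log_base: float = 2.0
    glcm_levels: int = 256
    glcm_distance: int = 1
    glcm_directions: str = "all13"
    glcm_moments_definition: str = "asm"
    sa_method: str = "mesh"
    # statistics
    alpha: float = 0.05
    normality_alpha: float = 0.05
    aggregate: str = "mean"
    cv_family_size: int = 4
    # optional dose inputs (mGy·cm per scan)
    dlp_mgy_cm: tuple[float, ...] | None = None
    dose_conversion_factor: float = 0.0145

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        kwargs = dict(d)
        for key in ("grid_shape", "spacing", "size_range_mm", "dlp_mgy_cm"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_file(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyResult:
    features: pd.DataFrame
    comparisons: dict[str, pd.DataFrame]
    cv_table: pd.DataFrame
    cv_comparisons: pd.DataFrame
    dose_summary: pd.DataFrame | None
    records: list[MeasurementRecord]
    config: StudyConfig
    config_hash: str
    logs: list[str] = field(default_factory=list)


def extract_features(
    volume: ImageVolume,
    roi: RoiMask,
    bins: int = 256,
    firstorder_log_base: float = 2.0,
    glcm_levels: int = 256,
    glcm_distance: int = 1,
    glcm_directions: str = "all13",
    glcm_moments_definition: str = "asm",
    sa_method: str = "mesh",
) -> FeatureVector:
    """Extract all 15 features for one (volume, mask) measurement."""
    values = masked_intensities(volume, roi)
    fo = firstorder_features(values, bins=bins, log_base=firstorder_log_base)
    sh = shape_features(roi, sa_method=sa_method)
    gl = glcm_features_from_roi(
        volume, roi, G=glcm_levels, distance=glcm_distance,
        directions=glcm_directions, moments_definition=glcm_moments_definition,
    )
    return FeatureVector(**fo.as_dict(), **sh, **gl.as_dict())


def _feature_kwargs(config: StudyConfig) -> dict:
    return dict(
        bins=config.bins,
        firstorder_log_base=config.firstorder_log_base,
        glcm_levels=config.glcm_levels,
        glcm_distance=config.glcm_distance,
        glcm_directions=config.glcm_directions,
        glcm_moments_definition=config.glcm_moments_definition,
        sa_method=config.sa_method,
    )


def simulate_lesion_images(
    config: StudyConfig, lesion_seed_sequence: np.random.SeedSequence
) -> tuple[dict[str, ImageVolume], dict[tuple[str, int], RoiMask]]:
    """Simulate one lesion: reconstruction variants and reader masks.

    Returns the three labelled volumes and the masks keyed (reader, session):
    reader R1 segments twice (intra-reader jitter), reader R2 once
    (inter-reader jitter); all segmentations are drawn on the ground truth,
    mirroring segmentation on FBP images.
    """
    rng = np.random.default_rng(lesion_seed_sequence)
    pspec = sample_phantom_spec(
        rng,
        grid_shape=tuple(config.grid_shape),
        spacing=tuple(config.spacing),
        size_mean_mm=config.size_mean_mm,
        size_sd_mm=config.size_sd_mm,
        size_range_mm=tuple(config.size_range_mm),
    )
    clean, truth = generate_phantom(pspec)
    rspec = ReconSpec(
        noise_sd_fbp=config.noise_sd_fbp,
        noise_correlation_length=config.noise_correlation_length,
        r_s3=config.r_s3,
        r_s5=config.r_s5,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    volumes = simulate_reconstructions(clean, rspec)

    def seeds(k: int) -> tuple[int, ...]:
        return tuple(int(rng.integers(0, 2**31 - 1)) for _ in range(k))

    reader1 = ReaderSpec("R1", config.intra_jitter_mm, session_seeds=seeds(2))
    masks: dict[tuple[str, int], RoiMask] = {
        ("R1", 1): simulate_reader(truth, reader1, session=1),
        ("R1", 2): simulate_reader(truth, reader1, session=2),
    }
    if config.n_readers >= 2:
        reader2 = ReaderSpec("R2", config.inter_jitter_mm, session_seeds=seeds(1))
        masks[("R2", 1)] = simulate_reader(truth, reader2, session=1)
    return volumes, masks


def simulate_study_records(config: StudyConfig) -> list[MeasurementRecord]:
    """Simulate the full study and extract features for every measurement.

    Each lesion yields len(masks) x 3 records (nine with two readers): every
    reader/session ROI is propagated unchanged across FBP, S3 and S5.
    """
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_lesions)
    kwargs = _feature_kwargs(config)
    records: list[MeasurementRecord] = []
    for li, child in enumerate(children):
        lesion_id = f"L{li + 1:03d}"
        volumes, masks = simulate_lesion_images(config, child)
        for (reader, session), mask in masks.items():
            pairs = propagate_roi(mask, volumes.values())
            for label, (vol, roi) in pairs.items():
                records.append(
                    MeasurementRecord(
                        lesion_id=lesion_id,
                        reader_id=reader,
                        session=session,
                        algorithm_label=label,
                        features=extract_features(vol, roi, **kwargs),
                    )
                )
    return records


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "lesion_id": rec.lesion_id,
            "reader_id": rec.reader_id,
            "session": rec.session,
            "algorithm_label": rec.algorithm_label,
        }
        row.update(rec.features.as_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(RECORD_COLUMNS) + list(FEATURE_NAMES))
    return df.sort_values(list(RECORD_COLUMNS)).reset_index(drop=True)


def frame_to_records(df: pd.DataFrame) -> list[MeasurementRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(
            MeasurementRecord(
                lesion_id=str(row["lesion_id"]),
                reader_id=str(row["reader_id"]),
                session=int(row["session"]),
                algorithm_label=str(row["algorithm_label"]),
                features=FeatureVector.from_dict(row),
            )
        )
    return records


def _algorithm_values(
    records: Sequence[MeasurementRecord], reader: str, session: int, feature: str
) -> dict[str, np.ndarray]:
    sub = [r for r in records if r.reader_id == reader and r.session == session]
    lesions = sorted({r.lesion_id for r in sub})
    labels = sorted({r.algorithm_label for r in sub})
    idx = {(r.lesion_id, r.algorithm_label): r for r in sub}
    missing = [
        (les, lab) for les in lesions for lab in labels if (les, lab) not in idx
    ]
    if missing:
        raise ValueError(f"incomplete algorithm triplets for reader {reader}: {missing}")
    order = [lab for lab in ("FBP", "S3", "S5") if lab in labels]
    order += [lab for lab in labels if lab not in order]
    return {
        lab: np.array([getattr(idx[(les, lab)].features, feature) for les in lesions])
        for lab in order
    }


def analyze_records(
    config: StudyConfig, records: Sequence[MeasurementRecord]
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame, list[str]]:
    """Algorithm comparisons per reader, CV table, and CV-source comparisons."""
    logs: list[str] = []
    readers = sorted({r.reader_id for r in records})
    if not records:
        raise ValueError("no measurement records to analyze")

    # --- Table 1/2 analogue: feature comparison across algorithms, per reader
    comparisons: dict[str, pd.DataFrame] = {}
    for reader in readers:
        rows = []
        for feature in FEATURE_NAMES:
            values = _algorithm_values(records, reader, 1, feature)
            if any(np.isnan(v).any() for v in values.values()):
                logs.append(f"{reader}/{feature}: NaN feature values, comparison skipped")
                continue
            omnibus, posthoc = vstats.compare_feature_across_algorithms(
                values, feature_name=feature,
                alpha=config.alpha, normality_alpha=config.normality_alpha,
            )
            row = {
                "feature": feature,
                "test": omnibus.test_used,
                "statistic": omnibus.statistic,
                "p_value": omnibus.p_value,
                "significant": omnibus.significant_after_correction,
            }
            for pair in posthoc:
                tag = pair.grouping.replace(" vs ", "_")
                row[f"p_{tag}"] = pair.p_value
                row[f"sig_{tag}"] = pair.significant_after_correction
            rows.append(row)
        comparisons[reader] = pd.DataFrame(rows)

    # --- Table 3 analogue: CV per feature and variability source
    sources = [s for s in vstats.VARIABILITY_SOURCES
               if not (s == "inter_reader" and len(readers) < 2)]
    if len(readers) < 2:
        logs.append("inter-reader analyses skipped: single reader in study")
    summaries = vstats.variability_table(
        records, sources=sources, aggregate=config.aggregate
    )
    cv_rows = []
    for feature in FEATURE_NAMES:
        row: dict = {"feature": feature}
        for source in sources:
            s = summaries[(feature, source)]
            # shape features are bitwise constant across propagated ROIs,
            # so inter-reconstruction CVs are exactly zero by construction
            row[f"cv_{source}"] = s.summary_cv
            row[f"category_{source}"] = s.category
        cv_rows.append(row)
    cv_table = pd.DataFrame(cv_rows)

    # --- CV comparisons between variability sources (Bonferroni family)
    cmp_rows = []
    for feature in FEATURE_NAMES:
        for src_a, src_b in CV_COMPARISON_PAIRS:
            if src_a not in sources or src_b not in sources:
                continue
            res = vstats.compare_variability_sources(
                summaries[(feature, src_a)].per_lesion_cv,
                summaries[(feature, src_b)].per_lesion_cv,
                feature_name=feature,
                grouping=f"{src_a} vs {src_b}",
                alpha=config.alpha,
                family_size=config.cv_family_size,
            )
            cmp_rows.append(
                {
                    "feature": feature,
                    "comparison": res.grouping,
                    "test": res.test_used,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "significant": res.significant_after_correction,
                    "alpha_corrected": res.alpha_corrected,
                }
            )
    cv_comparisons = pd.DataFrame(cmp_rows)
    return comparisons, cv_table, cv_comparisons, logs


def _dose_summary(config: StudyConfig) -> pd.DataFrame | None:
    if not config.dlp_mgy_cm:
        return None
    from .core import compute_effective_dose

    dlp = np.asarray(config.dlp_mgy_cm, dtype=float)
    eff = np.array([
        compute_effective_dose(d, config.dose_conversion_factor) for d in dlp
    ])
    return pd.DataFrame(
        {
            "quantity": ["dlp_mgy_cm", "effective_dose_msv"],
            "mean": [dlp.mean(), eff.mean()],
            "sd": [dlp.std(ddof=1) if dlp.size > 1 else 0.0,
                   eff.std(ddof=1) if eff.size > 1 else 0.0],
            "min": [dlp.min(), eff.min()],
            "max": [dlp.max(), eff.max()],
        }
    )


def run_study(config: StudyConfig, outdir: str | None = None) -> StudyResult:
    """Simulate, extract, analyze; optionally write the result bundle.

    Outputs (when ``outdir`` is given): ``features.csv`` (one row per
    lesion/reader/session/algorithm), ``comparisons_<reader>.csv``,
    ``cv_table.csv``, ``cv_comparisons.csv``, ``dose_summary.csv`` (if dose
    records were supplied), and ``metadata.json`` with the config, its hash,
    and per-feature test provenance.  Each CSV starts with a comment line
    carrying the config hash.
    """
    records = simulate_study_records(config)
    comparisons, cv_table, cv_comparisons, logs = analyze_records(config, records)
    chash = config.config_hash()
    result = StudyResult(
        features=records_to_frame(records),
        comparisons=comparisons,
        cv_table=cv_table,
        cv_comparisons=cv_comparisons,
        dose_summary=_dose_summary(config),
        records=records,
        config=config,
        config_hash=chash,
        logs=logs,
    )
    if outdir is not None:
        write_result_bundle(result, outdir)
    return result


def write_result_bundle(result: StudyResult, outdir: str) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    header = f"# config_hash={result.config_hash}\n"

    def _write(df: pd.DataFrame, name: str) -> None:
        path = os.path.join(outdir, name)
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False, lineterminator="\n")

    _write(result.features, "features.csv")
    for reader, df in result.comparisons.items():
        _write(df, f"comparisons_{reader}.csv")
    _write(result.cv_table, "cv_table.csv")
    _write(result.cv_comparisons, "cv_comparisons.csv")
    if result.dose_summary is not None:
        _write(result.dose_summary, "dose_summary.csv")
    meta = {
        "config": result.config.to_dict(),
        "config_hash": result.config_hash,
        "logs": result.logs,
        "feature_names": list(FEATURE_NAMES),
        "shape_features": list(SHAPE_FEATURE_NAMES),
        "conventions": {
            "firstorder_entropy_log_base": result.config.firstorder_log_base,
            "glcm_entropy_log_base": "e",
            "glcm_levels": result.config.glcm_levels,
            "glcm_distance": result.config.glcm_distance,
            "glcm_directions": result.config.glcm_directions,
            "surface_area_method": result.config.sa_method,
        },
    }
    with open(os.path.join(outdir, "metadata.json"), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
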