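"""Study orchestration: cohort -> features -> agreement statistics -> report.

The study design mirrors a three-parameter reproducibility analysis:

* SM (segmentation methods): three mask variants, reference gray level,
  reference image.
* GL (gray-level discretization): one designated mask (GBSV by default),
  gray levels {32, 64, 128, 256}, reference image.
* RA (reconstruction algorithms): the designated mask held fixed across the
  four image variants, reference gray level.

Cases failing the Dice inclusion floor on any mask pair are excluded and
logged.  A feature is reproducible for a parameter iff it passes the
``|d_bar|/SD`` gate for every pair of that parameter; the cross-parameter
set is the intersection over SM, GL, and RA.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement_stats as ag
from .discretize import DEFAULT_GRAY_LEVELS, REFERENCE_GRAY_LEVEL, discretize_roi
from .phantom import (
    DEFAULT_MASK_LABELS,
    CaseBundle,
    PhantomSpec,
    ReconProfile,
    generate_cohort,
)
from .shape_intensity_features import (
    IVH_FEATURE_NAMES,
    SHAPE_FEATURE_NAMES,
    ivh_features,
    shape_features,
)
from .texture_features import (
    GLCM_FEATURE_NAMES,
    GLRLM_FEATURE_NAMES,
    GLSZM_FEATURE_NAMES,
    NGTDM_FEATURE_NAMES,
    texture_features,
)
from .volio import FeatureTable, ROIMask, SUVVolume, read_mask, read_volume

__all__ = [
    "ALL_FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "StudyConfig",
    "ReproducibilityReport",
    "extract_features",
    "extract_cohort_features",
    "run_study",
    "load_cohort",
]

logger = logging.getLogger(__name__)

#: Catalogue families and the full 79-name catalogue.
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "glcm": GLCM_FEATURE_NAMES,
    "glrlm": GLRLM_FEATURE_NAMES,
    "glszm": GLSZM_FEATURE_NAMES,
    "ngtdm": NGTDM_FEATURE_NAMES,
    "shape": SHAPE_FEATURE_NAMES,
    "ivh": IVH_FEATURE_NAMES,
}
ALL_FEATURE_NAMES: tuple[str, ...] = tuple(
    itertools.chain.from_iterable(FEATURE_FAMILIES.values())
)


def extract_features(volume: SUVVolume, mask: ROIMask, ng: int) -> dict[str, float]:
    """All 79 catalogue features for one (volume, mask, gray level)."""
    d = discretize_roi(volume, mask, ng)
    feats: dict[str, float] = {}
    feats.update(texture_features(d))
    feats.update(shape_features(mask).features())
    feats.update(ivh_features(volume, mask, d).features())
    assert set(feats) == set(ALL_FEATURE_NAMES)
    return feats


@dataclass
class StudyConfig:
    """Design parameters of a reproducibility study."""

    n_cases: int = 10
    seed: int = 0
    input_dir: str | None = None  # None -> phantom mode
    gray_levels: tuple[int, ...] = DEFAULT_GRAY_LEVELS
    reference_gray_level: int = REFERENCE_GRAY_LEVEL
    mask_labels: tuple[str, ...] = DEFAULT_MASK_LABELS
    reference_mask: str = "MTV1"
    discretization_mask: str = "GBSV"  # mask used for the GL and RA studies
    reference_recon: str = "OSEM"
    sm_pairs: tuple[tuple[str, str], ...] = (
        ("MTV1", "MTV2"),
        ("MTV1", "GBSV"),
        ("MTV2", "GBSV"),
    )
    gl_pairs: tuple[tuple[int, int], ...] = ((64, 32), (64, 128), (64, 256))
    ra_pairs: tuple[tuple[str, str], ...] = (
        ("OSEM", "FOREIR"),
        ("OSEM", "FOREFBP"),
        ("OSEM", "3DRP"),
    )
    dice_floor: float = 0.75
    phantom_spec: PhantomSpec = field(default_factory=PhantomSpec)
    perturbation_mm: tuple[float, ...] = (2.5, 4.0, 3.0)
    recon_profiles: dict[str, ReconProfile] | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.dice_floor <= 1.0):
            raise ValueError(f"dice_floor must be in (0, 1], got {self.dice_floor}")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.reference_gray_level not in self.gray_levels:
            raise ValueError("reference gray level must be among gray_levels")
        for m, n in self.sm_pairs:
            if m not in self.mask_labels or n not in self.mask_labels:
                raise ValueError(f"SM pair {(m, n)} not covered by mask labels")
        for a, b in self.gl_pairs:
            if a != self.reference_gray_level:
                raise ValueError("every GL pair must lead with the reference gray level")
            if b not in self.gray_levels:
                raise ValueError(f"gray level {b} not in gray_levels")
        for a, _ in self.ra_pairs:
            if a != self.reference_recon:
                raise ValueError("every RA pair must lead with the reference recon")
        if self.discretization_mask not in self.mask_labels:
            raise ValueError("discretization_mask must be one of mask_labels")


@dataclass
class ReproducibilityReport:
    """Per-feature reproducibility statistics across all study parameters."""

    features: FeatureTable
    pair_stats: pd.DataFrame  # parameter, pair_label, feature_name, stats, level
    icc: pd.DataFrame  # parameter, feature_name, icc, ci bounds, precision
    dice_table: pd.DataFrame  # case_id, pair, dice, included
    excluded_cases: list[str]
    reproducible_sets: dict[str, list[str]]  # per parameter + "ALL"

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pair_stats": self.pair_stats.to_dict(orient="records"),
            "icc": self.icc.to_dict(orient="records"),
            "dice": self.dice_table.to_dict(orient="records"),
            "excluded_cases": self.excluded_cases,
            "reproducible_sets": self.reproducible_sets,
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=float))

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pair_stats.to_csv(out / "report_pairs.csv", index=False)
        self.icc.to_csv(out / "report_icc.csv", index=False)
        self.dice_table.to_csv(out / "report_dice.csv", index=False)


def load_cohort(input_dir: str | Path) -> list[CaseBundle]:
    """Load a cohort written by :func:`petrad.phantom.write_cohort`."""
    input_dir = Path(input_dir)
    manifest = json.loads((input_dir / "manifest.json").read_text())
    bundles = []
    for entry in manifest["cases"]:
        recons = {
            label: read_volume(input_dir / fn)
            for label, fn in entry["recon_variants"].items()
        }
        masks = {
            label: read_mask(input_dir / fn, label=label)
            for label, fn in entry["mask_variants"].items()
        }
        ref = next(iter(recons.values()))
        bundles.append(
            CaseBundle(
                case_id=entry["case_id"],
                spec=None,
                base_volume=ref,
                true_mask=None,
                recon_variants=recons,
                mask_variants=masks,
            )
        )
    return bundles


def _dice_filter(
    bundles: list[CaseBundle], floor: float
) -> tuple[list[CaseBundle], pd.DataFrame, list[str]]:
    rows = []
    kept, excluded = [], []
    for b in bundles:
        labels = list(b.mask_variants)
        ok = True
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                dc = ag.dice(b.mask_variants[labels[i]], b.mask_variants[labels[j]])
                rows.append(
                    {
                        "case_id": b.case_id,
                        "pair": f"{labels[i]}-{labels[j]}",
                        "dice": dc,
                    }
                )
                ok = ok and dc >= floor
        if ok:
            kept.append(b)
        else:
            excluded.append(b.case_id)
            logger.info("case %s excluded: Dice below floor %.2f", b.case_id, floor)
    table = pd.DataFrame(rows, columns=["case_id", "pair", "dice"])
    if len(table):
        table["included"] = ~table["case_id"].isin(excluded)
    return kept, table, excluded


def extract_cohort_features(bundles: list[CaseBundle], config: StudyConfig) -> FeatureTable:
    """Extract the union of (mask, gray level, recon) combinations the three
    study arms require, one row per feature value."""
    ref_gl = config.reference_gray_level
    ref_rc = config.reference_recon
    rows = []
    for b in bundles:
        combos: set[tuple[str, int, str]] = set()
        for m in config.mask_labels:
            combos.add((m, ref_gl, ref_rc))
        for gl in config.gray_levels:
            combos.add((config.discretization_mask, gl, ref_rc))
        for rc in b.recon_variants:
            combos.add((config.discretization_mask, ref_gl, rc))
        missing = [m for m, _, _ in combos if m not in b.mask_variants]
        missing += [rc for _, _, rc in combos if rc not in b.recon_variants]
        if missing:
            logger.warning("case %s missing variants %s; skipped", b.case_id, missing)
            continue
        for mask_label, gl, rc in sorted(combos):
            feats = extract_features(
                b.recon_variants[rc], b.mask_variants[mask_label], gl
            )
            for name, value in feats.items():
                rows.append(
                    {
                        "case_id": b.case_id,
                        "segmentation": mask_label,
                        "gray_level": gl,
                        "recon": rc,
                        "feature_name": name,
                        "value": value,
                    }
                )
    return FeatureTable(pd.DataFrame(rows))


def _study_slices(table: FeatureTable, config: StudyConfig) -> dict[str, FeatureTable]:
    return {
        "SM": table.subset(
            gray_level=config.reference_gray_level, recon=config.reference_recon
        ),
        "GL": table.subset(
            segmentation=config.discretization_mask, recon=config.reference_recon
        ),
        "RA": table.subset(
            segmentation=config.discretization_mask,
            gray_level=config.reference_gray_level,
        ),
    }


def analyze_features(table: FeatureTable, config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair statistics + classification, and per-parameter ICC tables."""
    slices = _study_slices(table, config)
    pair_defs = {"SM": config.sm_pairs, "GL": config.gl_pairs, "RA": config.ra_pairs}

    pair_rows = []
    for param, pairs in pair_defs.items():
        sub = slices[param]
        col = ag.PARAMETER_COLUMNS[param]
        for pair in pairs:
            for res in ag.paired_differences(sub, pair, variant_column=col):
                cls = ag.classify_reproducibility(res)
                pair_rows.append(
                    {
                        "parameter": param,
                        "pair_label": res.pair_label,
                        "feature_name": res.feature_name,
                        "d_mean": res.d_mean,
                        "d_mean_abs": res.d_mean_abs,
                        "sd": res.sd,
                        "lrl": res.lrl,
                        "url": res.url,
                        "level": cls.level,
                        "reproducible": cls.reproducible,
                        "n_cases": res.n_cases,
                        "n_excluded": res.n_excluded,
                    }
                )
    pair_stats = pd.DataFrame(pair_rows)

    icc_rows = []
    for param, sub in slices.items():
        for res in ag.icc_with_precision(sub, param):
            icc_rows.append(
                {
                    "parameter": param,
                    "feature_name": res.feature_name,
                    "icc": res.icc,
                    "ci_lb": res.ci_lb,
                    "ci_ub": res.ci_ub,
                    "precision": res.precision,
                    "n_cases": res.n_cases,
                    "n_raters": res.n_raters,
                }
            )
    icc = pd.DataFrame(icc_rows)
    return pair_stats, icc


def _reproducible_sets(pair_stats: pd.DataFrame) -> dict[str, list[str]]:
    sets: dict[str, set[str]] = {}
    for param, grp in pair_stats.groupby("parameter"):
        ok = grp.groupby("feature_name")["reproducible"].all()
        sets[param] = set(ok[ok].index)
    inter = set.intersection(*sets.values()) if sets else set()
    out = {k: sorted(v) for k, v in sets.items()}
    out["ALL"] = sorted(inter)
    return out


def run_study(config: StudyConfig) -> ReproducibilityReport:
    """Run the full design and return the reproducibility report."""
    if config.input_dir is not None:
        bundles = load_cohort(config.input_dir)
    else:
        bundles = generate_cohort(
            config.n_cases,
            base_spec=config.phantom_spec,
            seed=config.seed,
            perturbation_mm=config.perturbation_mm,
            profiles=config.recon_profiles,
            dice_floor=config.dice_floor,
            mask_labels=config.mask_labels,
        )
    kept, dice_table, excluded = _dice_filter(bundles, config.dice_floor)
    if not kept:
        raise RuntimeError("no cases survive the Dice inclusion floor")
    features = extract_cohort_features(kept, config)
    if not len(features):
        raise RuntimeError("no features extracted (all cases missing variants?)")
    pair_stats, icc = analyze_features(features, config)
    return ReproducibilityReport(
        features=features,
        pair_stats=pair_stats,
        icc=icc,
        dice_table=dice_table,
        excluded_cases=excluded,
        reproducible_sets=_reproducible_sets(pair_stats),
    )
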