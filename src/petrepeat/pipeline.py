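"""End-to-end analysis pipeline and configuration handling.

A single YAML (or dict) config drives the whole run:

.. code-block:: yaml

    seed: 7
    input:
      mode: synthetic          # or "images" or "table"
      table: features.csv      # mode=table
      image_pairs:             # mode=images
        - patient_id: P001
          suv_test: p1_test_suv.nii.gz
          labels_test: p1_test_labels.nii.gz
          suv_retest: p1_retest_suv.nii.gz
          labels_retest: p1_retest_labels.nii.gz
    cohort:                    # mode=synthetic; any CohortParams field
      n_patients: 22
    analysis:
      features: [suv_max, suv_mean, suv_total, volume_cc]
      thresholds_cc: [1.0, 1.5]
      icc_variant: two_way     # or one_way
      wcov_method: rms         # or pooled
      volume_statistic: mean   # or test
      max_distance_mm: 10.0
    output:
      dir: out
      plots: true

The pipeline generates or loads lesion features, matches lesions across time
points where needed, computes the stratified repeatability report and renders
it.  All randomness flows from ``seed``; with a fixed seed the CSV/JSON
outputs are byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .cohort import FEATURES, CohortParams, generate_paired_features
from .errors import ValidationError
from .features import extract_features, read_feature_csv, read_labeled_image
from .matching import DEFAULT_MAX_DISTANCE_MM, compute_centroids, match_lesions
from .repeatability import (
    DEFAULT_THRESHOLDS_CC,
    filter_by_volume,
    log_ratios,
    pairs_from_long,
    repeatability_table,
    variance_components,
)
from .reporting import bland_altman_series, render_report

__all__ = ["DEFAULT_CONFIG", "load_config", "validate_config", "build_pairs", "run_pipeline"]

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "input": {"mode": "synthetic"},
    "cohort": {},
    "analysis": {
        "features": list(FEATURES),
        "thresholds_cc": list(DEFAULT_THRESHOLDS_CC),
        "icc_variant": "two_way",
        "wcov_method": "rms",
        "volume_statistic": "mean",
        "max_distance_mm": DEFAULT_MAX_DISTANCE_MM,
    },
    "output": {"dir": "petrepeat_out", "plots": True},
}

_SCHEMA = {
    "seed": None,
    "input": {"mode", "table", "image_pairs"},
    "cohort": {f.name for f in dataclasses.fields(CohortParams)},
    "analysis": set(DEFAULT_CONFIG["analysis"]),
    "output": {"dir", "plots"},
}
_IMAGE_PAIR_KEYS = {"patient_id", "suv_test", "labels_test", "suv_retest", "labels_retest"}


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys.

    Raises :class:`ValidationError` listing every offending key.
    """
    bad = [k for k in config if k not in _SCHEMA]
    for section, allowed in _SCHEMA.items():
        if allowed is None or section not in config:
            continue
        sub = config[section]
        if not isinstance(sub, dict):
            bad.append(section)
            continue
        bad.extend(f"{section}.{k}" for k in sub if k not in allowed)
    if bad:
        raise ValidationError(f"unknown config keys: {sorted(bad)}")
    merged = {k: (v.copy() if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in config.items():
        if isinstance(v, dict):
            merged[k].update(v)
        else:
            merged[k] = v
    mode = merged["input"]["mode"]
    if mode not in ("synthetic", "images", "table"):
        raise ValidationError(f"input.mode must be synthetic|images|table, got {mode!r}")
    if mode == "table" and "table" not in merged["input"]:
        raise ValidationError("input.mode=table requires input.table")
    if mode == "images":
        pairs = merged["input"].get("image_pairs") or []
        for i, p in enumerate(pairs):
            missing = _IMAGE_PAIR_KEYS - set(p)
            if missing:
                raise ValidationError(f"input.image_pairs[{i}] missing keys {sorted(missing)}")
        if not pairs:
            raise ValidationError("input.mode=images requires input.image_pairs")
    return merged


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _pairs_from_images(image_pairs: list[dict], max_distance_mm: float) -> pd.DataFrame:
    """Extract + centroid-match each patient's scan pair into the wide table."""
    long_rows = []
    for spec in image_pairs:
        pid = str(spec["patient_id"])
        test = read_labeled_image(spec["suv_test"], spec["labels_test"], pid, "test")
        retest = read_labeled_image(spec["suv_retest"], spec["labels_retest"], pid, "retest")
        match = match_lesions(
            compute_centroids(test), compute_centroids(retest), max_distance_mm
        )
        if match.unmatched_test or match.unmatched_retest:
            logger.info(
                "patient %s: %d unmatched test / %d unmatched retest lesions excluded",
                pid,
                len(match.unmatched_test),
                len(match.unmatched_retest),
            )
        feats = {
            ("test", m.lesion_id): m for m in extract_features(test)
        } | {("retest", m.lesion_id): m for m in extract_features(retest)}
        for tl, rl, _ in match.matched:
            for tp, lid in (("test", tl), ("retest", rl)):
                m = feats[(tp, lid)]
                long_rows.append(
                    {
                        "patient_id": pid,
                        "lesion_id": f"{pid}-L{tl:03d}",  # matched lesion keyed by test label
                        "timepoint": tp,
                        "suv_max": m.suv_max,
                        "suv_mean": m.suv_mean,
                        "suv_total": m.suv_total,
                        "volume_cc": m.volume_cc,
                    }
                )
    if not long_rows:
        raise ValidationError("no matched lesions found in any image pair")
    return pairs_from_long(pd.DataFrame(long_rows))


def build_pairs(config: dict) -> pd.DataFrame:
    """Produce the matched-pair feature table for a validated config."""
    mode = config["input"]["mode"]
    if mode == "synthetic":
        params = CohortParams(**{**config["cohort"], "seed": config["seed"]})
        pairs, _ = generate_paired_features(params)
        return pairs
    if mode == "table":
        return pairs_from_long(read_feature_csv(config["input"]["table"]))
    return _pairs_from_images(
        config["input"]["image_pairs"], config["analysis"]["max_distance_mm"]
    )


def run_pipeline(config: dict | str | Path, out_dir: str | Path | None = None) -> dict:
    """Run generate/load -> match -> stratified statistics -> report.

    Returns the output manifest.  Non-plot outputs are byte-identical across
    runs with the same config and seed.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = validate_config(config)
    out = Path(out_dir if out_dir is not None else config["output"]["dir"])
    out.mkdir(parents=True, exist_ok=True)

    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("petrepeat")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("seed=%s config_sha256=%s", config["seed"], cfg_hash)
        logger.info("config=%s", json.dumps(config, sort_keys=True, default=str))
        pairs = build_pairs(config)
        ana = config["analysis"]
        strata = [("all", pairs)] + [
            (f">{t:g}cc", filter_by_volume(pairs, t, statistic=ana["volume_statistic"]))
            for t in ana["thresholds_cc"]
        ]
        for label, sub in strata:
            logger.info("stratum %s: %d lesions", label, len(sub))
        results = repeatability_table(
            pairs,
            features=ana["features"],
            thresholds_cc=ana["thresholds_cc"],
            icc_variant=ana["icc_variant"],
            wcov_method=ana["wcov_method"],
            volume_statistic=ana["volume_statistic"],
        )
        series = [
            bland_altman_series(sub, feature, variance_components(log_ratios(sub, feature)), label)
            for label, sub in strata
            if len(sub) >= 2
            for feature in ana["features"]
        ]
        return render_report(results, series, out, plots=config["output"]["plots"])
    finally:
        root.removeHandler(handler)
        handler.close()
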