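"""End-to-end workflow: extract per-cell features, classify, compare groups.

``run_extract`` walks each protocol in dependency order (passive features →
rheobase / first-AP features → train features → FS classification) and
returns one row per cell; cells without a rheobase are excluded with a
recorded reason, and per-cell failures are collected rather than aborting
the run.  ``run_compare`` produces two-group statistics per feature within
each FS class plus the per-animal FS-fraction aggregation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .classify import FS, NON_FS, ClassifierRule, aggregate_fs_fraction, classify_fs
from .passive import compute_passive_features
from .spikes import DetectionConfig, aps_in_step, extract_ap_features, find_rheobase
from .stats import WELCH, mann_whitney, two_sample_ttest
from .traces import JUNCTION_POTENTIAL_MV, StepProtocol
from .trains import TrainConfig, compute_train_features


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline, with the package defaults.

    Unknown keys in a config file are rejected rather than ignored.
    """

    junction_potential_mV: float = JUNCTION_POTENTIAL_MV
    rin_step_lo_pA: float = -20.0
    rin_step_hi_pA: float = -5.0
    tau_fit_window_ms: float = 200.0
    rin_steady_fraction: float = 0.2
    sag_steady_window_ms: float = 100.0
    dvdt_threshold: float = 10.0
    rise_guard_mV: float = 20.0
    refractory_ms: float = 1.0
    derivative_smooth_n: int = 1
    fahp_window_ms: float = 10.0
    min_initial_hz: float = 150.0
    min_ap_count: int = 100
    mahp_baseline_ms: float = 500.0
    mahp_search_ms: float = 500.0
    aphw_max_ms: float = 0.26
    ahp_min_mV: float = 16.5
    ar_min: float = 0.56
    min_conditions: int = 2
    ttest_variant: str = WELCH
    seed: int = 0

    def detection(self) -> DetectionConfig:
        return DetectionConfig(dvdt_threshold=self.dvdt_threshold,
                               rise_guard_mV=self.rise_guard_mV,
                               refractory_ms=self.refractory_ms,
                               derivative_smooth_n=self.derivative_smooth_n,
                               fahp_window_ms=self.fahp_window_ms)

    def train(self) -> TrainConfig:
        return TrainConfig(min_initial_hz=self.min_initial_hz,
                           min_ap_count=self.min_ap_count,
                           mahp_baseline_ms=self.mahp_baseline_ms,
                           mahp_search_ms=self.mahp_search_ms)

    def rule(self) -> ClassifierRule:
        return ClassifierRule(aphw_max_ms=self.aphw_max_ms,
                              ahp_min_mV=self.ahp_min_mV,
                              ar_min=self.ar_min,
                              min_conditions=self.min_conditions)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Feature columns compared between groups by default (Fig.-style report).
DEFAULT_COMPARE_FEATURES = [
    "rmp", "rin", "tau_m", "cin", "sag", "rheobase_pA", "v_threshold",
    "ap_amplitude", "half_width", "max_rise", "max_decay", "fahp",
    "initial_freq", "adaptation_ratio", "accommodation", "mahp", "fi_slope",
]


def _none_to_nan(x) -> float:
    return math.nan if x is None else float(x)


def extract_cell(protocol: StepProtocol, config: RunConfig = RunConfig(),
                 ) -> dict:
    """One CellRecord row (dict) for a protocol; raises on unusable cells."""
    det = config.detection()
    row: dict = {"cell_id": protocol.cell_id, "animal_id": protocol.animal_id,
                 "group_label": protocol.group_label, "exclusion": ""}
    pf = compute_passive_features(
        protocol, lo_pA=config.rin_step_lo_pA, hi_pA=config.rin_step_hi_pA,
        fit_window_ms=config.tau_fit_window_ms,
        steady_fraction=config.rin_steady_fraction,
        sag_steady_window_ms=config.sag_steady_window_ms)
    row.update(rmp=pf.rmp, rin=pf.rin, tau_m=pf.tau_m, cin=pf.cin, sag=pf.sag)

    rheo = find_rheobase(protocol, det)
    if rheo is None:
        row["exclusion"] = "no rheobase: no sweep evoked an AP"
        return row
    ap = rheo.first_ap
    row.update(rheobase_pA=rheo.rheobase_pA, v_threshold=ap.v_threshold,
               ap_amplitude=ap.amplitude, half_width=ap.half_width,
               max_rise=ap.max_rise, max_decay=ap.max_decay,
               fahp=_none_to_nan(ap.fahp))

    events = {}
    for k, sweep in enumerate(protocol.sweeps):
        if sweep.step.amplitude_pA > 0:
            events[k] = aps_in_step(sweep, extract_ap_features(sweep, det))
    tf = compute_train_features(protocol, det, config.train(),
                                events_per_sweep=events)
    row.update(fi_slope=tf.fi_slope, initial_freq=tf.initial_freq,
               steady_freq=tf.steady_freq,
               adaptation_ratio=_none_to_nan(tf.adaptation_ratio),
               accommodation=_none_to_nan(tf.accommodation),
               mahp=_none_to_nan(tf.mahp),
               analysis_sweep_index=tf.analysis_sweep_index,
               qualifies=tf.qualifies, n_aps=tf.n_aps)

    fs_class, met = classify_fs(row["half_width"], row["fahp"],
                                row["adaptation_ratio"], config.rule())
    row.update(fs_class=fs_class if fs_class is not None else "unclassifiable",
               conditions_met=met)
    return row


def run_extract(protocols: Sequence[StepProtocol],
                config: RunConfig = RunConfig(),
                ) -> tuple[pd.DataFrame, list[str]]:
    """CellRecord table for a list of protocols.

    Returns the table and a list of per-cell error messages (the run
    continues past individual failures; failed cells appear with an
    exclusion reason when partially extractable, or only in the error list
    otherwise).
    """
    rows, errors = [], []
    for protocol in protocols:
        try:
            rows.append(extract_cell(protocol, config))
        except Exception as exc:  # noqa: BLE001 - per-cell isolation
            errors.append(f"{protocol.cell_id}: {exc}")
    table = pd.DataFrame(rows)
    return table, errors


def run_compare(table: pd.DataFrame,
                features: Sequence[str] = DEFAULT_COMPARE_FEATURES,
                config: RunConfig = RunConfig(),
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-group comparisons per feature within each FS class.

    Returns ``(comparisons, fs_fractions)``.  The comparison table has one
    row per (fs_class, feature) with the group summaries and the test
    result; FS and non-FS cells are analysed separately.
    """
    groups = sorted(table["group_label"].unique())
    if len(groups) < 2:
        raise ValueError("group comparison requires at least two groups")
    if len(groups) > 2:
        raise ValueError(f"exactly two groups expected, got {groups}")
    g1, g2 = groups
    rows = []
    for fs_class in (FS, NON_FS):
        sub = table[table["fs_class"] == fs_class]
        for feat in features:
            if feat not in sub.columns:
                continue
            x = sub.loc[sub["group_label"] == g1, feat].dropna().to_numpy()
            y = sub.loc[sub["group_label"] == g2, feat].dropna().to_numpy()
            if x.size < 2 or y.size < 2:
                continue
            if config.ttest_variant == "mann_whitney":
                cmp_ = mann_whitney(x, y, feature=feat)
            else:
                cmp_ = two_sample_ttest(x, y, config.ttest_variant,
                                        feature=feat)
            rows.append({"fs_class": fs_class, "feature": feat,
                         f"mean_{g1}": cmp_.mean1, f"mean_{g2}": cmp_.mean2,
                         f"sem_{g1}": cmp_.sem1, f"sem_{g2}": cmp_.sem2,
                         f"n_{g1}": cmp_.n1, f"n_{g2}": cmp_.n2,
                         "statistic": cmp_.statistic, "df": cmp_.df,
                         "p": cmp_.p, "test_variant": cmp_.test_variant})
    comparisons = pd.DataFrame(rows)
    fractions = aggregate_fs_fraction(table)
    return comparisons, fractions


def run_manifest(config: RunConfig, input_paths: Sequence[str | Path] = (),
                 ) -> dict:
    """Reproducibility manifest: config hash plus input-file hashes."""
    cfg = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {"config_sha256": hashlib.sha256(cfg.encode()).hexdigest(),
                "inputs": {}}
    for p in input_paths:
        p = Path(p)
        manifest["inputs"][p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return manifest
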