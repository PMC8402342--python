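"""Synthetic multi-cohort, three-class expression study generator.

Real host-response marker-swap studies pool dozens of heterogeneous cohorts
profiled on different platforms into training and validation compendia of
bacterial / viral / noninfected samples.  This module generates
copy-number-scale expression matrices with the same statistical skeleton —
per-marker class-conditional fold changes with coded directionality, additive
log-scale cohort batch effects, log-normal biological noise and a
limit-of-detection floor — so that every downstream stage (QC filtering,
forward selection, band-metric evaluation) is testable without any download.

The generative model for sample *s* of class *c* in cohort *g* and marker *m* is

    copies[s, m] = max(floor, 2 ** (b_m + delta_{c,m} + u_{g,m} + eps_s))

with per-marker log2 baseline ``b_m ~ N(mu_b, sd_b)``, class effect
``delta_{c,m}`` taken from an :func:`effect table <build_effect_table>`
(log2 fold change of the class versus the noninfected control), cohort batch
shift ``u_{g,m} ~ N(0, sd_batch)`` and residual noise
``eps ~ N(0, sd_resid)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CLASSES = ("bacterial", "viral", "noninfected")

#: Canonical direction codes, ordered from strong induction to strong repression.
DIRECTION_CODES = ("up_strong", "up", "none", "down", "down_strong")

#: Accepted aliases for direction codes (arrow glyphs as printed in marker tables).
_DIRECTION_ALIASES = {
    "↑↑": "up_strong",
    "↑": "up",
    "↓": "down",
    "↓↓": "down_strong",
    "": "none",
    "-": "none",
    "none": "none",
    "up_strong": "up_strong",
    "up": "up",
    "down": "down",
    "down_strong": "down_strong",
}

#: Default mapping of direction codes to signed log2 fold changes.  The source
#: marker tables code direction and relative strength, not magnitudes; these
#: values make the percentile fold-change filter and the classifiers exercise
#: realistically and are plain configuration.
DEFAULT_MAGNITUDES: Mapping[str, float] = {
    "up_strong": 1.5,
    "up": 0.75,
    "none": 0.0,
    "down": -0.75,
    "down_strong": -1.5,
}

#: The 29-marker host-response diagnostic panel with coded effect directions
#: in the three clinical contrasts: bacterial vs. uninfected (bi_uc), viral
#: vs. uninfected (vi_uc) and bacterial vs. viral (bi_vi).
PANEL_DIRECTIONS: Mapping[str, tuple[str, str, str]] = {
    "ARG1": ("up_strong", "up", "up"),
    "BATF": ("up_strong", "up", "up"),
    "C3AR1": ("up_strong", "up", "up"),
    "CD163": ("up_strong", "up", "up"),
    "CEACAM1": ("up_strong", "up", "up"),
    "CTSB": ("up_strong", "up", "up"),
    "CTSL": ("up_strong", "up", "up"),
    "DEFA4": ("up_strong", "up", "up"),
    "FAM214A": ("down_strong", "down", "down"),
    "FURIN": ("up_strong", "up", "up"),
    "GADD45A": ("up_strong", "up", "up"),
    "GNA15": ("up_strong", "up", "up"),
    "HK3": ("up_strong", "up", "up"),
    "HLA-DMB": ("down_strong", "down", "down"),
    "IFI27": ("up", "up_strong", "down"),
    "ISG15": ("down", "up", "down"),
    "JUP": ("down", "up", "down"),
    "KCNJ2": ("up_strong", "up", "up"),
    "LY86": ("down", "up", "down"),
    "NMRK1": ("up_strong", "up", "up"),
    "OASL": ("up", "up_strong", "down"),
    "OLFM4": ("up_strong", "up", "up"),
    "PDE4B": ("down_strong", "down", "down"),
    "PER1": ("up_strong", "down", "up"),
    "PSMB9": ("down", "up", "down"),
    "RAPGEF1": ("down_strong", "down", "down"),
    "S100A12": ("up_strong", "up", "up"),
    "TGFBI": ("down_strong", "down", "down"),
    "ZDHHC19": ("up_strong", "up", "up"),
}

DEFAULT_HOUSEKEEPERS = ("HKG1", "HKG2", "HKG3")


def default_panel_manifest() -> pd.DataFrame:
    """Marker manifest for the built-in 29-marker panel plus 3 housekeepers.

    Columns: ``marker``, ``role`` in {original, housekeeping}, ``gdna_pass``,
    ``dir_bi_uc``, ``dir_vi_uc``, ``dir_bi_vi``.
    """
    rows = [
        {
            "marker": m,
            "role": "original",
            "gdna_pass": 1,
            "dir_bi_uc": d[0],
            "dir_vi_uc": d[1],
            "dir_bi_vi": d[2],
        }
        for m, d in PANEL_DIRECTIONS.items()
    ]
    rows += [
        {
            "marker": h,
            "role": "housekeeping",
            "gdna_pass": 1,
            "dir_bi_uc": "none",
            "dir_vi_uc": "none",
            "dir_bi_vi": "none",
        }
        for h in DEFAULT_HOUSEKEEPERS
    ]
    return pd.DataFrame(rows)


def _canon_direction(code: object, marker: str) -> str:
    if code is None or (isinstance(code, float) and np.isnan(code)):
        return "none"
    key = str(code).strip()
    canon = _DIRECTION_ALIASES.get(key) or _DIRECTION_ALIASES.get(key.lower())
    if canon is None:
        raise ValueError(f"unknown direction code {key!r} for marker {marker!r}")
    return canon


def build_effect_table(
    manifest: pd.DataFrame,
    magnitude_map: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Materialize per-marker log2 class effects from coded directions.

    Parameters
    ----------
    manifest:
        Marker table with columns ``marker``, ``dir_bi_uc``, ``dir_vi_uc`` and
        optionally ``dir_bi_vi``; arrow glyphs and canonical codes are both
        accepted.
    magnitude_map:
        Direction code -> signed log2 fold change.  Defaults to
        :data:`DEFAULT_MAGNITUDES`.

    Returns
    -------
    DataFrame indexed by marker with columns ``lfc_bacterial`` and
    ``lfc_viral`` (log2 fold change of each infected class versus the
    noninfected control).

    Raises
    ------
    ValueError
        On an unknown direction code, or when a supplied bacterial-vs-viral
        direction contradicts the sign of (bacterial effect - viral effect).
    """
    mags = dict(DEFAULT_MAGNITUDES if magnitude_map is None else magnitude_map)
    mags.setdefault("none", 0.0)
    records = {}
    for _, row in manifest.iterrows():
        marker = str(row["marker"])
        d_bi = _canon_direction(row.get("dir_bi_uc"), marker)
        d_vi = _canon_direction(row.get("dir_vi_uc"), marker)
        for code in (d_bi, d_vi):
            if code not in mags:
                raise ValueError(
                    f"magnitude map has no entry for code {code!r} (marker {marker!r})"
                )
        lfc_b, lfc_v = float(mags[d_bi]), float(mags[d_vi])
        if "dir_bi_vi" in row.index:
            d_bv = _canon_direction(row.get("dir_bi_vi"), marker)
            diff = lfc_b - lfc_v
            expected = np.sign(mags.get(d_bv, 0.0))
            if d_bv != "none" and np.sign(diff) != expected:
                raise ValueError(
                    f"marker {marker!r}: coded bacterial-vs-viral direction {d_bv!r} "
                    f"contradicts effect difference {diff:+.3g}"
                )
        records[marker] = (lfc_b, lfc_v)
    table = pd.DataFrame.from_dict(
        records, orient="index", columns=["lfc_bacterial", "lfc_viral"]
    )
    table.index.name = "marker"
    return table


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic generator.

    Defaults emulate a scaled-down multi-cohort compendium: 8 cohorts of 25
    samples per class (600 samples in total), the last two cohorts held out as
    validation, baseline abundance around 2**10 = 1024 copies with 1.5 log2
    units of between-marker spread, 0.35 log2 units of cohort batch shift,
    0.7 log2 units of residual biological noise, and a 1-copy detection floor.
    """

    n_cohorts: int = 8
    samples_per_class_per_cohort: int = 25
    n_noise_markers: int = 0
    baseline_log2_median: float = 10.0
    baseline_log2_sd: float = 1.5
    cohort_batch_sd: float = 0.35
    residual_noise_sd: float = 0.7
    detection_floor: float = 1.0
    housekeeping_marker_names: Sequence[str] = DEFAULT_HOUSEKEEPERS
    seed: int = 0
    split_assignment: Mapping[str, str] | None = None
    classes: Sequence[str] = CLASSES

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ValueError("n_cohorts must be >= 1")
        if self.samples_per_class_per_cohort < 1:
            raise ValueError("samples_per_class_per_cohort must be >= 1")
        for name in ("baseline_log2_sd", "cohort_batch_sd", "residual_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be >= 0")
        if self.n_noise_markers < 0:
            raise ValueError("n_noise_markers must be >= 0")

    def cohort_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_cohorts)]

    def resolved_split(self) -> dict[str, str]:
        """Cohort -> split map; by default the last quarter (at least one
        cohort when there are two or more) is held out as validation."""
        cohorts = self.cohort_ids()
        if self.split_assignment is not None:
            split = {c: str(self.split_assignment[c]) for c in cohorts}
        else:
            n_val = max(1, self.n_cohorts // 4) if self.n_cohorts >= 2 else 0
            split = {
                c: ("validation" if i >= self.n_cohorts - n_val else "train")
                for i, c in enumerate(cohorts)
            }
        bad = sorted(set(split.values()) - {"train", "validation"})
        if bad:
            raise ValueError(f"invalid split labels: {bad}")
        if "train" not in split.values():
            raise ValueError("no cohort assigned to the train split")
        return split


def simulate_study(
    config: SimConfig, effects: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-cohort three-class expression study.

    Parameters
    ----------
    config:
        :class:`SimConfig`; ``config.seed`` drives a root
        :class:`numpy.random.SeedSequence` from which one substream per cohort
        (plus one for marker-level parameters) is spawned deterministically.
    effects:
        Effect table from :func:`build_effect_table`.  Markers listed in
        ``config.housekeeping_marker_names`` but absent from the table are
        appended with zero effects, as are ``NOISE_###`` filler markers.

    Returns
    -------
    (matrix, annotation):
        ``matrix`` is a samples x markers DataFrame of copy-number-scale
        values (floored at ``detection_floor``); ``annotation`` has columns
        ``sample_id``, ``class``, ``cohort_id``, ``split``.
    """
    config.validate()
    effects = effects.copy()
    for hk in config.housekeeping_marker_names:
        if hk in effects.index:
            if (effects.loc[hk] != 0).any():
                raise ValueError(f"housekeeping marker {hk!r} has nonzero effects")
        else:
            effects.loc[hk] = (0.0, 0.0)
    for i in range(config.n_noise_markers):
        effects.loc[f"NOISE_{i + 1:03d}"] = (0.0, 0.0)

    markers = list(effects.index)
    if len(set(markers)) != len(markers):
        raise ValueError("duplicate markers in effect table")
    classes = list(config.classes)
    split = config.resolved_split()

    root = np.random.SeedSequence(config.seed)
    marker_stream, *cohort_streams = root.spawn(config.n_cohorts + 1)
    marker_rng = np.random.default_rng(marker_stream)
    baselines = marker_rng.normal(
        config.baseline_log2_median, config.baseline_log2_sd, size=len(markers)
    )
    # housekeepers sit at the common baseline so normalization is stable
    hk_mask = np.isin(markers, list(config.housekeeping_marker_names))
    baselines[hk_mask] = config.baseline_log2_median

    class_effect = np.zeros((len(classes), len(markers)))
    for ci, cls in enumerate(classes):
        if cls == "bacterial":
            class_effect[ci] = effects["lfc_bacterial"].to_numpy()
        elif cls == "viral":
            class_effect[ci] = effects["lfc_viral"].to_numpy()

    blocks, ann_rows = [], []
    n_per = config.samples_per_class_per_cohort
    for cohort, stream in zip(config.cohort_ids(), cohort_streams):
        rng = np.random.default_rng(stream)
        batch = rng.normal(0.0, config.cohort_batch_sd, size=len(markers))
        for ci, cls in enumerate(classes):
            eps = rng.normal(0.0, config.residual_noise_sd, size=(n_per, len(markers)))
            log2_vals = baselines + class_effect[ci] + batch + eps
            blocks.append(np.maximum(2.0**log2_vals, config.detection_floor))
            ann_rows += [
                {
                    "sample_id": f"{cohort}_{cls[:3]}_{j + 1:03d}",
                    "class": cls,
                    "cohort_id": cohort,
                    "split": split[cohort],
                }
                for j in range(n_per)
            ]

    annotation = pd.DataFrame(ann_rows)
    matrix = pd.DataFrame(
        np.vstack(blocks), index=annotation["sample_id"].to_numpy(), columns=markers
    )
    matrix.index.name = "sample_id"
    matrix.columns.name = "marker"
    return matrix, annotation


def planted_design(
    n_informative: int = 5,
    n_noise: int = 45,
    lfc: float = 1.5,
    samples_per_class_per_cohort: int = 60,
    n_cohorts: int = 5,
    seed: int = 0,
    **overrides,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Study with a known ground truth: a few informative markers in a sea of noise.

    Informative markers ``INF_##`` alternate bacterial- and viral-driven
    effects of magnitude ``lfc`` (log2) so that no single class is trivially
    linearly separable from the others with one marker; noise markers carry no
    class signal.  Returns (matrix, annotation, informative_marker_names).
    """
    # distinct effect patterns so every planted marker adds non-redundant
    # class information: bacterial-only, viral-only, down-regulated and
    # discordant responses, cycled
    patterns = [
        (lfc, 0.0),
        (0.0, lfc),
        (-lfc, 0.0),
        (0.0, -lfc),
        (lfc, -lfc),
        (-lfc, lfc),
        (lfc, lfc / 2),
        (lfc / 2, lfc),
    ]
    rows = [
        (f"INF_{i + 1:02d}", *patterns[i % len(patterns)])
        for i in range(n_informative)
    ]
    effects = pd.DataFrame(
        {m: (b, v) for m, b, v in rows},
        index=["lfc_bacterial", "lfc_viral"],
    ).T
    effects.index.name = "marker"
    cfg = SimConfig(
        n_cohorts=n_cohorts,
        samples_per_class_per_cohort=samples_per_class_per_cohort,
        n_noise_markers=n_noise,
        seed=seed,
        **overrides,
    )
    matrix, annotation = simulate_study(cfg, effects)
    return matrix, annotation, [m for m, _, _ in rows]
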