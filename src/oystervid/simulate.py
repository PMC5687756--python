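"""Synthetic towed-video survey data.

Two generators share the hierarchical layout of :class:`~oystervid.design.SurveyDesign`:

* :func:`generate_vc_dataset` draws reading-level values from the Gaussian
  mixed model itself (site fixed effects plus Normal random effects for
  transect, section, observer and their interactions). This is the exact
  data-generating process assumed by the ANOVA/REML estimators, so parameter
  recovery can be tested against known truth.
* :func:`generate_field_truth` / :func:`generate_video_observations` form a
  mechanistic pipeline: integer oysters are placed in sections from a latent
  hierarchical mean, then "read" imperfectly — each oyster is detected per
  (observer, reading) pass with a status-conditional probability and, if
  detected, may be assigned the wrong live/dead status. Detected living
  oysters are split into "probably living" and "possibly living" scoring
  categories.

All randomness descends from the single root seed in
:class:`~oystervid.design.GeneratorConfig`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import GeneratorConfig, SurveyDesign, VarianceComponents

__all__ = [
    "generate_vc_dataset",
    "generate_field_truth",
    "generate_video_observations",
    "section_index",
]

READING_COLUMNS = [
    "site",
    "transect",
    "section",
    "observer",
    "reading",
    "count_probably_living",
    "count_possibly_living",
    "count_dead",
]

TRUTH_COLUMNS = [
    "site",
    "transect",
    "section",
    "true_living",
    "true_dead",
    "vegetation_cover",
]

OYSTER_COLUMNS = ["oyster_id", "field_status", "video_status"]

TRUE_OYSTER_COLUMNS = [
    "oyster_id",
    "site",
    "transect",
    "section",
    "status",
    "in_cluster",
    "covered",
]

# fixed sub-stream tags so each stage draws from its own reproducible stream
_STREAM_TRUTH = 0
_STREAM_VIDEO = 1
_STREAM_VC = 2


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    if not isinstance(config.seed, (int, np.integer)):
        raise ValueError("seed must be an integer")
    return np.random.default_rng([int(config.seed), stream])


def _layout(design: SurveyDesign) -> dict[str, np.ndarray]:
    """Per-section label and index arrays for the nested layout."""
    t = np.asarray(design.transects_per_site)
    b = design.sections_per_transect
    T = int(t.sum())
    tr_site = np.repeat(np.arange(design.n_sites), t)  # global transect -> site
    tr_label = np.concatenate([np.arange(1, ti + 1) for ti in t])
    return {
        "site": np.repeat(tr_site + 1, b),
        "transect": np.repeat(tr_label, b),
        "section": np.tile(np.arange(1, b + 1), T),
        "site_idx": np.repeat(tr_site, b),
        "tr_idx": np.repeat(np.arange(T), b),
        "n_transects": T,
    }


def section_index(design: SurveyDesign) -> pd.DataFrame:
    """One row per (site, transect, section), 1-based labels."""
    lay = _layout(design)
    return pd.DataFrame(
        {"site": lay["site"], "transect": lay["transect"], "section": lay["section"]}
    )


def _site_effects(values, n_sites: int, label: str) -> np.ndarray:
    eff = np.asarray(values, dtype=float)
    if eff.shape != (n_sites,):
        raise ValueError(f"{label} must have one entry per site ({n_sites})")
    return eff


def generate_vc_dataset(design: SurveyDesign, config: GeneratorConfig) -> pd.DataFrame:
    """Reading-level data from the Gaussian variance-component model.

    Each reading is ``grand_mean + site + Tr(Si) + Se(Tr,Si) + Ob + Ob*Si +
    Tr(Si)*Ob + Se(Tr,Si)*Ob + e`` with every random term Normal with its
    configured variance. Values are emitted in ``count_probably_living`` and
    may be non-integer (the model is Gaussian on counts).
    """
    if config.mode != "gaussian-vc":
        raise ValueError("generate_vc_dataset requires mode='gaussian-vc'")
    rng = _rng(config, _STREAM_VC)
    vc = config.vc
    site_eff = _site_effects(config.site_effects, design.n_sites, "site_effects")

    lay = _layout(design)
    n_sec = lay["site"].size
    c, n = design.observers, design.readings_per_observer
    sec_site = lay["site_idx"]
    tr_id = lay["tr_idx"]
    n_tr = lay["n_transects"]

    sd = {k: np.sqrt(v) for k, v in vc.as_dict().items()}
    tr_eff = rng.normal(0.0, sd["s_tr2"], n_tr)
    se_eff = rng.normal(0.0, sd["s_se2"], n_sec)
    ob_eff = rng.normal(0.0, sd["s_ob2"], c)
    obsi_eff = rng.normal(0.0, sd["s_obsi2"], (design.n_sites, c))
    trob_eff = rng.normal(0.0, sd["s_trob2"], (n_tr, c))
    seob_eff = rng.normal(0.0, sd["s_seob2"], (n_sec, c))
    resid = rng.normal(0.0, sd["s_e2"], (n_sec, c, n))

    base = config.grand_mean + site_eff[sec_site] + tr_eff[tr_id] + se_eff  # (n_sec,)
    y = (
        base[:, None, None]
        + ob_eff[None, :, None]
        + obsi_eff[sec_site][:, :, None]
        + trob_eff[tr_id][:, :, None]
        + seob_eff[:, :, None]
        + resid
    )

    rep = c * n
    out = pd.DataFrame(
        {
            "site": np.repeat(lay["site"], rep),
            "transect": np.repeat(lay["transect"], rep),
            "section": np.repeat(lay["section"], rep),
            "observer": np.tile(np.repeat(np.arange(1, c + 1), n), n_sec),
            "reading": np.tile(np.arange(1, n + 1), n_sec * c),
            "count_probably_living": y.reshape(-1),
            "count_possibly_living": 0.0,
            "count_dead": 0.0,
        }
    )
    return out[READING_COLUMNS]


def _latent_counts(
    rng: np.random.Generator,
    design: SurveyDesign,
    grand_mean: float,
    site_effects: np.ndarray,
    vc: VarianceComponents,
    count_model: str,
) -> np.ndarray:
    """Per-section integer counts from the latent hierarchical mean."""
    lay = _layout(design)
    sec_site = lay["site_idx"]
    tr_id = lay["tr_idx"]

    tr_eff = rng.normal(0.0, np.sqrt(vc.s_tr2), lay["n_transects"])
    se_eff = rng.normal(0.0, np.sqrt(vc.s_se2), sec_site.size)
    latent = grand_mean + site_effects[sec_site] + tr_eff[tr_id] + se_eff
    latent = np.clip(latent, 0.0, None)
    if count_model == "poisson":
        return rng.poisson(latent).astype(int)
    return np.rint(latent).astype(int)


def generate_field_truth(
    design: SurveyDesign, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Field census: per-section true counts and individually placed oysters.

    Living counts come from a latent hierarchical mean (grand mean + fixed
    site offset + Normal transect and section effects), floored at zero and
    rounded; the dead-oyster process is parameterized independently. Returns
    ``(section_truth, true_oysters)``.
    """
    if config.mode != "mechanistic":
        raise ValueError("generate_field_truth requires mode='mechanistic'")
    rng = _rng(config, _STREAM_TRUTH)
    site_eff = _site_effects(config.site_effects, design.n_sites, "site_effects")
    if config.grand_mean + site_eff.min() < 0:
        raise ValueError("grand_mean + min(site_effects) must be >= 0")
    dead_site_eff = (
        site_eff
        if config.dead_site_effects is None
        else _site_effects(config.dead_site_effects, design.n_sites, "dead_site_effects")
    )
    dead_vc = config.dead_vc if config.dead_vc is not None else config.vc

    sections = section_index(design).copy()
    living = _latent_counts(
        rng, design, config.grand_mean, site_eff, config.vc, config.count_model
    )
    dead = _latent_counts(
        rng, design, config.dead_grand_mean, dead_site_eff, dead_vc, config.count_model
    )
    sections["true_living"] = living
    sections["true_dead"] = dead
    sections["vegetation_cover"] = rng.uniform(0.0, 1.0, len(sections))

    n_total = int(living.sum() + dead.sum())
    oy = pd.concat(
        [
            sections.loc[sections.index.repeat(living), ["site", "transect", "section"]],
            sections.loc[sections.index.repeat(dead), ["site", "transect", "section"]],
        ]
    ).reset_index(drop=True)
    oy["status"] = np.repeat(["living", "dead"], [living.sum(), dead.sum()])
    oy.insert(0, "oyster_id", np.arange(1, n_total + 1))
    oy["in_cluster"] = rng.random(n_total) < config.p_in_cluster
    oy["covered"] = rng.random(n_total) < config.p_covered
    return sections[TRUTH_COLUMNS], oy[TRUE_OYSTER_COLUMNS]


def generate_video_observations(
    truth: tuple[pd.DataFrame, pd.DataFrame],
    design: SurveyDesign,
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Imperfect video reading of a field census.

    For every (observer, reading, oyster) the oyster is detected with the
    status-conditional probability (reduced by ``covered_detect_multiplier``
    for covered oysters); detected oysters are misclassified with the
    configured probabilities, and oysters scored living are split into the
    "probably"/"possibly" categories. Returns ``(readings, oyster_records)``;
    the matched oyster records use observer 1, reading 1 — an oyster is
    matchable only if that pass detected it.
    """
    if config.mode != "mechanistic":
        raise ValueError("generate_video_observations requires mode='mechanistic'")
    _, oysters = truth
    rng = _rng(config, _STREAM_VIDEO)
    c, n = design.observers, design.readings_per_observer

    n_oy = len(oysters)
    is_living = (oysters["status"] == "living").to_numpy()
    p_det = np.where(is_living, config.p_detect_living, config.p_detect_dead)
    covered = oysters["covered"].to_numpy(dtype=bool)
    p_det = np.where(covered, p_det * config.covered_detect_multiplier, p_det)
    p_flip = np.where(
        is_living, config.p_live_classified_dead, config.p_dead_classified_living
    )

    detected = rng.random((n_oy, c, n)) < p_det[:, None, None]
    flipped = rng.random((n_oy, c, n)) < p_flip[:, None, None]
    video_living = detected & (is_living[:, None, None] ^ flipped)
    video_dead = detected & ~(is_living[:, None, None] ^ flipped)
    probably = video_living & (
        rng.random((n_oy, c, n)) < config.p_probably_given_detected_living
    )
    possibly = video_living & ~probably

    key = oysters[["site", "transect", "section"]]
    frames = []
    for ob in range(c):
        for rd in range(n):
            agg = key.copy()
            agg["count_probably_living"] = probably[:, ob, rd].astype(int)
            agg["count_possibly_living"] = possibly[:, ob, rd].astype(int)
            agg["count_dead"] = video_dead[:, ob, rd].astype(int)
            summed = agg.groupby(["site", "transect", "section"], as_index=False).sum()
            summed["observer"] = ob + 1
            summed["reading"] = rd + 1
            frames.append(summed)
    counts = pd.concat(frames, ignore_index=True)
    # ensure sections with zero oysters still appear
    readings = section_index(design).merge(
        pd.DataFrame(
            [(o, r) for o in range(1, c + 1) for r in range(1, n + 1)],
            columns=["observer", "reading"],
        ),
        how="cross",
    )
    readings = readings.merge(
        counts, on=["site", "transect", "section", "observer", "reading"], how="left"
    ).fillna(0)
    for col in ("count_probably_living", "count_possibly_living", "count_dead"):
        readings[col] = readings[col].astype(int)
    readings = readings.sort_values(
        ["site", "transect", "section", "observer", "reading"]
    ).reset_index(drop=True)

    # matched individual oysters: first observer's first reading
    seen = detected[:, 0, 0]
    vid_status = np.where(video_living[:, 0, 0], "living", "dead")
    records = pd.DataFrame(
        {
            "oyster_id": oysters.loc[seen, "oyster_id"].to_numpy(),
            "field_status": oysters.loc[seen, "status"].to_numpy(),
            "video_status": vid_status[seen],
        }
    )
    return readings[READING_COLUMNS], records[OYSTER_COLUMNS]
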