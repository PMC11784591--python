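"""Causal-site selection, effect-size draws and frequency-dependent scaling.

This is the first stage of the phenotype pipeline: pick causal sites on
the ARG (uniformly at random, or user-supplied), pick a causal allele at
each, draw a raw effect size per site from the trait model, and scale it
by ``(2 p (1-p))^(alpha/2)`` where ``p`` is the causal-allele frequency
among sample nodes.  Negative ``alpha`` up-weights rare variants, the
classic frequency-dependent architecture of complex traits; ``alpha=0``
leaves effect sizes untouched.

The output is a tidy trait table with one row per (causal site, trait).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import arg as _arg
from ._seed import SeedLike, as_generator, as_seed_sequence
from .trait_model import ModelLike, as_model

__all__ = [
    "TRAIT_TABLE_COLUMNS",
    "eligible_alleles",
    "eligible_sites",
    "select_causal_sites",
    "choose_causal_allele",
    "frequency_scale",
    "sim_trait",
]

TRAIT_TABLE_COLUMNS = [
    "site_id", "position", "causal_allele", "raw_beta", "scaled_beta",
    "allele_freq", "trait_id",
]


def eligible_alleles(arg: _arg.ArgTables, site: int) -> list[tuple[str, float]]:
    """Derived alleles at ``site`` segregating in the samples.

    Returns ``(allele, frequency)`` pairs for every distinct derived state
    whose sample frequency lies strictly inside (0, 1); alleles fixed or
    absent in the samples carry no association signal and the frequency
    scaling is degenerate for them.
    """
    ancestral = str(arg.sites["ancestral_state"].iloc[site])
    derived = sorted(
        set(arg.mutations.loc[arg.mutations["site"] == site, "derived_state"])
        - {ancestral}
    )
    out = []
    for allele in derived:
        p = _arg.allele_frequency(arg, site, allele)
        if 0.0 < p < 1.0:
            out.append((allele, p))
    return out


def eligible_sites(arg: _arg.ArgTables) -> list[int]:
    """Site ids with at least one segregating derived allele."""
    return [s for s in range(arg.num_sites) if eligible_alleles(arg, s)]


def select_causal_sites(
    arg: _arg.ArgTables, num_causal: int, rng: SeedLike = None
) -> list[int]:
    """Sample ``num_causal`` eligible sites uniformly without replacement,
    returned sorted by position (site id order)."""
    rng = as_generator(rng)
    if num_causal < 1:
        raise ValueError(f"num_causal must be positive, got {num_causal}")
    pool = eligible_sites(arg)
    if num_causal > len(pool):
        raise ValueError(
            f"requested {num_causal} causal sites but only {len(pool)} "
            f"eligible sites exist")
    chosen = rng.choice(len(pool), size=num_causal, replace=False)
    return sorted(pool[i] for i in chosen)


def choose_causal_allele(
    arg: _arg.ArgTables,
    site: int,
    rng: SeedLike = None,
    *,
    frequency_weighted: bool = False,
) -> str:
    """Pick the causal allele at ``site``.

    Uniform over eligible derived alleles by default; with
    ``frequency_weighted=True`` alleles are picked proportionally to their
    sample frequency.
    """
    rng = as_generator(rng)
    alleles = eligible_alleles(arg, site)
    if not alleles:
        raise ValueError(
            f"site {site} has no derived allele segregating in the samples")
    if frequency_weighted:
        weights = np.array([p for _, p in alleles])
        idx = rng.choice(len(alleles), p=weights / weights.sum())
    else:
        idx = rng.choice(len(alleles))
    return alleles[int(idx)][0]


def frequency_scale(raw_beta, p, alpha: float):
    """Scale an effect size by ``(2 p (1-p))^(alpha/2)``.

    ``p`` must lie strictly in (0, 1): the factor is 0 or undefined at the
    boundaries (and blows up there for negative ``alpha``).
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError(f"allele frequency must lie strictly in (0, 1), got {p}")
    factor = (2.0 * p * (1.0 - p)) ** (alpha / 2.0)
    return np.asarray(raw_beta) * factor


def _resolve_explicit_sites(arg: _arg.ArgTables, causal_sites) -> pd.DataFrame:
    """Normalise a user-supplied causal-site specification.

    Accepts a sequence of site ids, or a DataFrame with a ``position``
    column plus optional ``causal_allele`` and ``raw_beta`` columns (the
    CSV interchange format).  Returns a frame with columns
    ``site_id, causal_allele (nullable), raw_beta (nullable)``.
    """
    if isinstance(causal_sites, pd.DataFrame):
        df = causal_sites.copy()
        if "site_id" not in df.columns:
            if "position" not in df.columns:
                raise ValueError(
                    "explicit causal sites need a 'site_id' or 'position' column")
            positions = arg.sites["position"].to_numpy()
            site_ids = []
            for pos in df["position"]:
                hits = np.nonzero(positions == float(pos))[0]
                if len(hits) != 1:
                    raise ValueError(f"no unique site at position {pos}")
                site_ids.append(int(hits[0]))
            df["site_id"] = site_ids
        out = pd.DataFrame({"site_id": df["site_id"].astype(int)})
        out["causal_allele"] = (
            df["causal_allele"].astype(str)
            if "causal_allele" in df.columns else None)
        out["raw_beta"] = (
            df["raw_beta"].astype(float) if "raw_beta" in df.columns else np.nan)
        return out.reset_index(drop=True)
    site_ids = [int(s) for s in causal_sites]
    return pd.DataFrame({
        "site_id": site_ids,
        "causal_allele": [None] * len(site_ids),
        "raw_beta": [np.nan] * len(site_ids),
    })


def sim_trait(
    arg: _arg.ArgTables,
    model: ModelLike,
    *,
    num_causal: int = 1,
    causal_sites=None,
    alpha: float = 0.0,
    random_seed: SeedLike = None,
    frequency_weighted_alleles: bool = False,
) -> pd.DataFrame:
    """Simulate causal sites and effect sizes for an ARG.

    Parameters
    ----------
    arg
        The ARG tables.
    model
        A :class:`~argtrait.trait_model.TraitModel` (or model name).  A
        multivariate model makes each causal site pleiotropic: one joint
        draw is shared across its ``k`` traits.
    num_causal
        Number of causal sites to sample uniformly among eligible sites
        (ignored when ``causal_sites`` is given).
    causal_sites
        Explicit causal sites: a list of site ids, or a DataFrame with
        ``position`` (or ``site_id``) and optional ``causal_allele`` /
        ``raw_beta`` columns.  Missing alleles are chosen at random,
        missing effect sizes drawn from the model.
    alpha
        Strength of frequency dependence; each site's raw effect size is
        multiplied by ``(2 p (1-p))^(alpha/2)``.
    random_seed
        Master seed; split into (site-selection, allele-choice,
        effect-size) substreams in that fixed order.

    Returns
    -------
    DataFrame with columns ``site_id, position, causal_allele, raw_beta,
    scaled_beta, allele_freq, trait_id`` — one row per (site, trait),
    ordered by trait then position.
    """
    model = as_model(model)
    if not np.isfinite(alpha):
        raise ValueError(f"alpha must be finite, got {alpha}")
    ss = as_seed_sequence(random_seed)
    site_rng, allele_rng, effect_rng = map(np.random.default_rng, ss.spawn(3))

    if causal_sites is None:
        spec = pd.DataFrame({
            "site_id": select_causal_sites(arg, num_causal, site_rng),
            "causal_allele": None,
            "raw_beta": np.nan,
        })
    else:
        spec = _resolve_explicit_sites(arg, causal_sites)
        for sid in spec["site_id"]:
            if not 0 <= sid < arg.num_sites:
                raise ValueError(f"explicit causal site {sid} does not exist")
        spec = spec.sort_values("site_id", kind="stable").reset_index(drop=True)

    rows = []
    k = model.num_traits
    for r in spec.itertuples(index=False):
        site = int(r.site_id)
        position = float(arg.sites["position"].iloc[site])
        allele = r.causal_allele
        if allele is None or (isinstance(allele, float) and np.isnan(allele)):
            allele = choose_causal_allele(
                arg, site, allele_rng, frequency_weighted=frequency_weighted_alleles)
        p = _arg.allele_frequency(arg, site, str(allele))
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"causal allele '{allele}' at site {site} has sample "
                f"frequency {p}; it must segregate (0 < p < 1)")
        if np.isnan(r.raw_beta):
            raw = model.draw(effect_rng)
        else:
            raw = np.full(k, float(r.raw_beta))
        scaled = frequency_scale(raw, p, alpha)
        for trait_id in range(k):
            rows.append((site, position, str(allele), float(raw[trait_id]),
                         float(scaled[trait_id]), p, trait_id))

    df = pd.DataFrame(rows, columns=TRAIT_TABLE_COLUMNS)
    df = df.sort_values(["trait_id", "position"], kind="stable")
    return df.reset_index(drop=True)
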