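"""Heritability-calibrated environmental noise and the one-shot
phenotype simulator.

Given per-individual genetic values G with population variance V_G and a
user-supplied narrow-sense heritability h², environmental noise is drawn
i.i.d. per individual from Normal(0, V_G (1 - h²) / h²) and the phenotype
is G + E.  In expectation the realized heritability Var(G)/Var(G+E) then
equals the request.  With h² = 1 (or V_G = 0) the noise is exactly zero.
Multi-trait noise is independent across traits: pleiotropy enters only
through the joint effect-size distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np
import pandas as pd

from ._seed import SeedLike, as_generator, as_seed_sequence
from .arg import ArgTables
from .genetic_value import genetic_values
from .trait_model import ModelLike, as_model
from .trait_sim import sim_trait

__all__ = [
    "PHENOTYPE_COLUMNS",
    "PhenotypeResult",
    "genetic_variance",
    "sim_env",
    "sim_phenotype",
]

PHENOTYPE_COLUMNS = [
    "individual_id", "trait_id", "genetic_value", "environmental_noise",
    "phenotype",
]

H2Like = Union[float, Mapping[int, float], np.ndarray, list]


def genetic_variance(values: pd.DataFrame, trait_id: int = 0) -> float:
    """Population variance (denominator n) of genetic values for one trait."""
    g = values.loc[values["trait_id"] == trait_id, "genetic_value"].to_numpy()
    if len(g) == 0:
        raise ValueError(f"no individuals for trait {trait_id}")
    return float(np.var(g))


def _h2_for_trait(h2: H2Like, trait_id: int, trait_ids) -> float:
    if isinstance(h2, Mapping):
        try:
            value = h2[trait_id]
        except KeyError:
            raise ValueError(f"h2 not provided for trait {trait_id}") from None
    elif isinstance(h2, (list, tuple, np.ndarray)):
        arr = np.asarray(h2, dtype=float)
        if len(arr) != len(trait_ids):
            raise ValueError(
                f"h2 has {len(arr)} entries for {len(trait_ids)} traits")
        value = arr[list(trait_ids).index(trait_id)]
    else:
        value = h2
    value = float(value)
    if not 0.0 < value <= 1.0:
        raise ValueError(f"h2 must lie in (0, 1], got {value}")
    return value


def sim_env(
    values: pd.DataFrame, h2: H2Like, random_seed: SeedLike = None
) -> pd.DataFrame:
    """Add environmental noise to per-individual genetic values.

    Parameters
    ----------
    values
        DataFrame ``individual_id, trait_id, genetic_value``.
    h2
        Narrow-sense heritability in (0, 1]; a scalar applied to all
        traits, or a per-trait sequence/mapping.
    random_seed
        Seed for the noise stream.

    Returns
    -------
    DataFrame ``individual_id, trait_id, genetic_value,
    environmental_noise, phenotype`` with phenotype = G + E exactly.
    """
    if len(values) == 0:
        raise ValueError("genetic-value table is empty")
    rng = as_generator(random_seed)
    trait_ids = sorted(set(int(t) for t in values["trait_id"]))
    frames = []
    for trait_id in trait_ids:
        sub = values[values["trait_id"] == trait_id]
        g = sub["genetic_value"].to_numpy(dtype=float)
        h2_t = _h2_for_trait(h2, trait_id, trait_ids)
        v_g = float(np.var(g))
        env_var = v_g * (1.0 - h2_t) / h2_t
        e = rng.normal(0.0, np.sqrt(env_var), size=len(g)) if env_var > 0 \
            else np.zeros(len(g))
        frames.append(pd.DataFrame({
            "individual_id": sub["individual_id"].to_numpy(),
            "trait_id": np.int64(trait_id),
            "genetic_value": g,
            "environmental_noise": e,
            "phenotype": g + e,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out[PHENOTYPE_COLUMNS]


@dataclass
class PhenotypeResult:
    """Bundle returned by :func:`sim_phenotype`: the simulated effect
    sizes and the per-individual phenotypes."""

    trait: pd.DataFrame
    phenotype: pd.DataFrame


def sim_phenotype(
    arg: ArgTables,
    model: ModelLike,
    *,
    num_causal: int = 1,
    causal_sites=None,
    alpha: float = 0.0,
    h2: H2Like = 0.3,
    random_seed: SeedLike = None,
    frequency_weighted_alleles: bool = False,
) -> PhenotypeResult:
    """One-shot phenotype simulation: sim_trait → genetic_values → sim_env.

    The master seed is split into a trait substream and a noise substream
    in that order, so the three-stage pipeline called manually with those
    substreams reproduces this function exactly.
    """
    ss = as_seed_sequence(random_seed)
    trait_ss, env_ss = ss.spawn(2)
    traits = sim_trait(
        arg, model, num_causal=num_causal, causal_sites=causal_sites,
        alpha=alpha, random_seed=trait_ss,
        frequency_weighted_alleles=frequency_weighted_alleles,
    )
    values = genetic_values(arg, traits)
    phenotypes = sim_env(values, h2, random_seed=env_ss)
    return PhenotypeResult(trait=traits, phenotype=phenotypes)
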