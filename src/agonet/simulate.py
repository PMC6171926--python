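"""Synthetic herd generator with planted network-trait effects.

Emulates the study design the analysis pipeline assumes: 78 single-sex,
single-breed pens of 15 pigs (3 pigs from each of 5 litters), weights
around N(27.6, 5.6^2) kg, and roughly 62 fights plus 57 bullying bouts
per pen in the first 24 h after mixing.  Lesion counts are generated
from a planted linear model on pen-level network traits (largest
fighting-clique size, fighting betweenness centralisation, mean fight
duration) plus breed, batch and residual noise, so that the full
statistical pipeline can be validated by parameter recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .metrics import betweenness_centrality, freeman_centralisation, largest_clique_size
from .networks import binary_adjacency, build_pen_network

__all__ = ["HerdConfig", "generate_herd", "sample_pen_interactions"]

SECONDS_PER_DAY = 86_400

SEXES = ("female", "intact male", "castrated male")

# pen-mean lesion intercepts at the reference trait values, chosen on the
# scale of typical commercial post-mixing outcomes (acute 24 h deltas are
# larger and more variable than chronic 3 wk counts)
DELTA_24H_INTERCEPT = {"anterior": 18.0, "central": 9.0, "posterior": 4.0}
RAW_3WK_INTERCEPT = {"anterior": 10.0, "central": 10.0, "posterior": 4.4}
REGIONS = ("anterior", "central", "posterior")

# reference points the planted effects are centred on, so changing an
# effect size does not shift the overall lesion level
REF_CLIQUE = 4.5
REF_BETWEENNESS = 0.15
REF_FIGHT_DURATION = 15.0


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class HerdConfig:
    """Parameters of the simulated herd; defaults are the study design."""

    n_pens: int = 78
    pen_size: int = 15
    n_litters_per_pen: int = 5
    pigs_per_litter: int = 3
    weight_mean: float = 27.6  # kg
    weight_sd: float = 5.6  # kg
    fight_rate_mean: float = 62.38  # fights per pen per 24 h
    fight_rate_sd: float = 24.0
    bully_rate_mean: float = 57.0
    bully_rate_sd: float = 26.4
    n_batches: int = 14
    # planted effects (lesions per unit trait); zero them for a null herd
    effect_clique_3wk: float = -2.0
    effect_betweenness_3wk: float = 15.0
    effect_fightdur_24h: float = 0.2
    breed_effect_3wk: float = 1.0  # purebred excess at 3 wk
    batch_sd: float = 1.5  # lesions
    residual_sd: float = 2.0  # lesions
    # behaviour shape
    attachment_skew: float = 0.3  # 0 = uniform partners, 1 = one pig in every event
    injurious_fraction: float = 0.2  # fraction of fights fought at injurious bite rate
    purebred_fraction: float = 0.6
    short_pen: bool = False  # make the first pen 14 pigs (one animal removed)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pen_size != self.n_litters_per_pen * self.pigs_per_litter:
            raise ConfigurationError(
                f"pen_size {self.pen_size} != n_litters_per_pen x pigs_per_litter "
                f"({self.n_litters_per_pen} x {self.pigs_per_litter})"
            )
        if self.n_pens < 1:
            raise ConfigurationError("n_pens must be >= 1")
        for name in (
            "weight_sd",
            "fight_rate_mean",
            "fight_rate_sd",
            "bully_rate_mean",
            "bully_rate_sd",
            "batch_sd",
            "residual_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.attachment_skew <= 1:
            raise ConfigurationError("attachment_skew must lie in [0, 1]")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")

    def null(self) -> "HerdConfig":
        """Copy of this configuration with every planted effect set to zero."""
        return replace(
            self,
            effect_clique_3wk=0.0,
            effect_betweenness_3wk=0.0,
            effect_fightdur_24h=0.0,
            breed_effect_3wk=0.0,
        )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated at zero by rejection (negligible for these rates)."""
    out = rng.normal(mean, sd, size)
    while True:
        bad = out < 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, bad.sum())


def sample_pen_interactions(
    pen_roster: pd.DataFrame,
    n_fights: int,
    n_bullies: int,
    rng: np.random.Generator,
    skew: float = 0.3,
    injurious_fraction: float = 0.2,
) -> pd.DataFrame:
    """Sample one pen's 24 h event log.

    Partner choice follows a simple attachment scheme: with probability
    ``skew`` the first participant is the pen's designated top aggressor
    (its first pig), otherwise uniform; the partner is always uniform
    among the rest.  At ``skew=1`` one pig takes part in every event,
    producing a maximally centralised (star-like) network.

    Fight durations are lognormal with median 15 s, bullying bouts with
    median 8 s, both at least 1 s.  A fraction ``injurious_fraction`` of
    fights carries a bite rate at or above 1 per 3 s; bite counts are
    rounded so the injurious classification survives the rounding.
    """
    pigs = pen_roster["pig_id"].to_numpy()
    n = len(pigs)
    if n < 2 and (n_fights or n_bullies):
        raise ValueError("cannot sample interactions in a pen with fewer than 2 pigs")
    if n_fights < 0 or n_bullies < 0:
        raise ValueError("event counts must be >= 0")
    m = n_fights + n_bullies
    if m == 0:
        return pd.DataFrame(
            columns=[
                "pen_id", "initiator", "receiver", "behaviour",
                "start_time", "duration", "bite_count",
            ]
        )

    hot = rng.random(m) < skew
    first = np.where(hot, 0, rng.integers(0, n, m))
    second = rng.integers(0, n - 1, m)
    second = second + (second >= first)

    behaviour = np.array(["fight"] * n_fights + ["bully"] * n_bullies)
    duration = np.empty(m)
    duration[:n_fights] = np.maximum(
        1.0, np.rint(rng.lognormal(math.log(15.0), 0.8, n_fights))
    )
    duration[n_fights:] = np.maximum(
        1.0, np.rint(rng.lognormal(math.log(8.0), 0.8, n_bullies))
    )
    bite_count = np.full(m, np.nan)
    if n_fights:
        injurious = rng.random(n_fights) < injurious_fraction
        rate = np.where(
            injurious,
            rng.uniform(1 / 3, 0.7, n_fights),
            rng.uniform(0.02, 0.30, n_fights),
        )
        # ceil keeps injurious fights at >= 1/3 bites/s; floor keeps the rest below
        bites = np.where(
            injurious,
            np.ceil(rate * duration[:n_fights]),
            np.floor(rate * duration[:n_fights]),
        )
        bite_count[:n_fights] = bites

    start = np.sort(rng.integers(0, SECONDS_PER_DAY, m))
    events = pd.DataFrame(
        {
            "pen_id": pen_roster["pen_id"].iloc[0],
            "initiator": pigs[first],
            "receiver": pigs[second],
            "behaviour": behaviour,
            "start_time": start,
            "duration": duration,
            "bite_count": bite_count,
        }
    )
    return events


def _make_roster(config: HerdConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for p in range(config.n_pens):
        pen_id = f"pen{p:03d}"
        sex = SEXES[p % len(SEXES)]
        # deterministic striping reproduces the herd's breed mix exactly
        breed = (
            "purebred"
            if (p % 5) < round(5 * config.purebred_fraction)
            else "crossbred"
        )
        batch_id = f"batch{p * config.n_batches // config.n_pens:02d}"
        size = config.pen_size
        if config.short_pen and p == 0:
            size -= 1
        weights = np.maximum(0.5, rng.normal(config.weight_mean, config.weight_sd, size))
        for j in range(size):
            rows.append(
                {
                    "pig_id": f"{pen_id}_p{j:02d}",
                    "pen_id": pen_id,
                    "litter_id": f"{pen_id}_L{j // config.pigs_per_litter + 1}",
                    "sex": sex,
                    "breed": breed,
                    "weight": round(float(weights[j]), 2),
                    "batch_id": batch_id,
                }
            )
    return pd.DataFrame(rows)


def _pen_fight_traits(pen_events: pd.DataFrame, pen_roster: pd.DataFrame, pen_id: str) -> dict:
    """Fighting-network traits the lesion model is planted on."""
    net = build_pen_network(pen_events, pen_roster, pen_id, "fight")
    adj = binary_adjacency(net)
    if net.n_edges == 0:
        clique, betw = 1.0, 0.0
    else:
        clique = float(largest_clique_size(adj))
        betw = freeman_centralisation(betweenness_centrality(adj, directed=False))
    fights = pen_events[pen_events["behaviour"] == "fight"]
    mean_dur = float(fights["duration"].mean()) if len(fights) else REF_FIGHT_DURATION
    return {"clique": clique, "betweenness": betw, "mean_fight_duration": mean_dur}


def generate_herd(
    config: HerdConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (roster, events, lesions) for one synthetic herd.

    Deterministic for a fixed ``config.seed``.  Pen-mean lesions follow
    the planted linear model; pig-level counts are a multinomial split of
    the implied pen total with mildly overdispersed (Dirichlet) shares,
    since the analysis itself only consumes pen means.
    """
    rng = np.random.default_rng(config.seed)
    roster = _make_roster(config, rng)
    pen_ids = roster["pen_id"].drop_duplicates().tolist()

    n_f = np.rint(
        _truncated_normal(rng, config.fight_rate_mean, config.fight_rate_sd, len(pen_ids))
    ).astype(int)
    n_b = np.rint(
        _truncated_normal(rng, config.bully_rate_mean, config.bully_rate_sd, len(pen_ids))
    ).astype(int)

    roster_by_pen = dict(tuple(roster.groupby("pen_id", sort=False)))
    event_frames = {}
    for i, pen_id in enumerate(pen_ids):
        event_frames[pen_id] = sample_pen_interactions(
            roster_by_pen[pen_id],
            int(n_f[i]),
            int(n_b[i]),
            rng,
            skew=config.attachment_skew,
            injurious_fraction=config.injurious_fraction,
        )
    events = pd.concat(event_frames.values(), ignore_index=True)

    # batch effects drawn once per batch per timepoint x region
    batches = sorted(roster["batch_id"].unique())
    batch_eff = {
        (tp, region): dict(zip(batches, rng.normal(0.0, config.batch_sd, len(batches))))
        for tp in ("24h", "3wk")
        for region in REGIONS
    }

    lesion_rows = []
    for pen_id in pen_ids:
        pen_roster = roster_by_pen[pen_id]
        n = len(pen_roster)
        batch = pen_roster["batch_id"].iloc[0]
        breed = pen_roster["breed"].iloc[0]
        traits = _pen_fight_traits(event_frames[pen_id], pen_roster, pen_id)

        pre = rng.poisson(2.0, (n, len(REGIONS)))
        raw24 = np.zeros_like(pre)
        raw3 = np.zeros_like(pre)
        alpha = np.full(n, 5.0)  # mild overdispersion in the pig-level split
        for r, region in enumerate(REGIONS):
            mu24 = (
                DELTA_24H_INTERCEPT[region]
                + batch_eff[("24h", region)][batch]
                + config.effect_fightdur_24h
                * (traits["mean_fight_duration"] - REF_FIGHT_DURATION)
                + rng.normal(0.0, config.residual_sd)
            )
            mu3 = (
                RAW_3WK_INTERCEPT[region]
                + (config.breed_effect_3wk if breed == "purebred" else 0.0)
                + batch_eff[("3wk", region)][batch]
                + config.effect_clique_3wk * (traits["clique"] - REF_CLIQUE)
                + config.effect_betweenness_3wk * (traits["betweenness"] - REF_BETWEENNESS)
                + rng.normal(0.0, config.residual_sd)
            )
            total24 = max(0, int(round(mu24 * n + pre[:, r].sum())))
            total3 = max(0, int(round(mu3 * n)))
            w = rng.dirichlet(alpha)
            raw24[:, r] = rng.multinomial(total24, w)
            w = rng.dirichlet(alpha)
            raw3[:, r] = rng.multinomial(total3, w)

        pig_ids = pen_roster["pig_id"].to_numpy()
        for tp, counts in (("pre", pre), ("24h", raw24), ("3wk", raw3)):
            lesion_rows.append(
                pd.DataFrame(
                    {
                        "pig_id": pig_ids,
                        "timepoint": tp,
                        "anterior": counts[:, 0],
                        "central": counts[:, 1],
                        "posterior": counts[:, 2],
                    }
                )
            )
    lesions = pd.concat(lesion_rows, ignore_index=True)
    lesions = lesions.sort_values(
        ["pig_id", "timepoint"], kind="stable", ignore_index=True
    )
    return roster, events, lesions
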