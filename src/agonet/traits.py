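"""Dyadic behavioural traits: per-pig summaries of direct interactions.

Dyadic traits summarise only an animal's own fights and bullying bouts,
in contrast with network properties which capture indirect structure.
Six traits are computed per pig and averaged to pen level:

- mean duration of fighting and bullying (all bouts the pig was in)
- total fight duration (seconds)
- number of fights involved in, regardless of who initiated
- proportion of fight time spent in injurious fighting (bites delivered
  at a rate of at least 1 per 3 s)
- duration of bullying given (pig was initiator)
- duration of bullying received (pig was receiver)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "INJURIOUS_BITE_RATE",
    "classify_injurious",
    "pig_dyadic_traits",
    "pen_dyadic_means",
    "dyadic_trait_table",
]

# bites per second; fights at or above this rate are injurious
INJURIOUS_BITE_RATE = 1.0 / 3.0

TRAIT_COLUMNS = [
    "mean_duration_fight_bully",
    "total_fight_duration",
    "n_fights",
    "prop_injurious_fight_time",
    "bully_given_duration",
    "bully_received_duration",
]


class MissingBiteCountWarning(UserWarning):
    pass


def classify_injurious(event, bite_count: float | None = None) -> bool:
    """True iff bites were delivered at >= 1 per 3 s (boundary inclusive).

    Accepts either an event record (mapping with ``duration`` and
    ``bite_count``) or the two values directly.
    """
    if bite_count is None and hasattr(event, "__getitem__") and not np.isscalar(event):
        duration, bite_count = float(event["duration"]), event["bite_count"]
    else:
        duration = float(event)
    if duration <= 0:
        raise ValueError("fight duration must be positive")
    if bite_count is None or (isinstance(bite_count, float) and np.isnan(bite_count)):
        raise ValueError("bite_count missing: injuriousness undefined")
    return bite_count / duration >= INJURIOUS_BITE_RATE


def _pen_events(events: pd.DataFrame, pen_id: str) -> pd.DataFrame:
    return events[events["pen_id"] == pen_id]


def pig_dyadic_traits(events: pd.DataFrame, pig_id: str) -> pd.Series:
    """Dyadic trait vector for one pig from its pen's event log.

    A pig with no recorded aggression scores zero on every trait.  If any
    of the pig's fights lacks a bite count the injurious-time proportion
    is reported as missing (NaN) with a warning.
    """
    involved = events[(events["initiator"] == pig_id) | (events["receiver"] == pig_id)]
    fights = involved[involved["behaviour"] == "fight"]
    bullies = involved[involved["behaviour"] == "bully"]

    out = pd.Series(0.0, index=TRAIT_COLUMNS, name=pig_id)
    n_bouts = len(involved)
    if n_bouts:
        out["mean_duration_fight_bully"] = involved["duration"].sum() / n_bouts
    out["total_fight_duration"] = fights["duration"].sum()
    out["n_fights"] = float(len(fights))
    out["bully_given_duration"] = bullies.loc[bullies["initiator"] == pig_id, "duration"].sum()
    out["bully_received_duration"] = bullies.loc[bullies["receiver"] == pig_id, "duration"].sum()

    total_fight_time = out["total_fight_duration"]
    if total_fight_time > 0:
        bites = fights["bite_count"] if "bite_count" in fights else pd.Series(np.nan, fights.index)
        if bites.isna().any():
            warnings.warn(
                f"pig {pig_id!r}: fight(s) missing bite_count, "
                "injurious-fighting proportion reported as missing",
                MissingBiteCountWarning,
                stacklevel=2,
            )
            out["prop_injurious_fight_time"] = np.nan
        else:
            injurious = bites.to_numpy() / fights["duration"].to_numpy() >= INJURIOUS_BITE_RATE
            out["prop_injurious_fight_time"] = (
                fights["duration"].to_numpy()[injurious].sum() / total_fight_time
            )
    return out


def pen_dyadic_means(events: pd.DataFrame, roster: pd.DataFrame, pen_id: str) -> pd.Series:
    """Arithmetic mean of each pig-level trait over the pen's full roster.

    Pigs with no aggression contribute zeros, so a quiet pen pulls every
    mean down; the divisor is the pen's actual roster size.
    """
    pigs = roster.loc[roster["pen_id"] == pen_id, "pig_id"].tolist()
    if not pigs:
        raise ValueError(f"pen {pen_id!r} has no pigs in the roster")
    known = set(pigs)
    ev = _pen_events(events, pen_id)
    bad = set(ev["initiator"]) | set(ev["receiver"])
    if bad - known:
        raise ValueError(f"pen {pen_id!r}: events reference unknown pigs {sorted(bad - known)}")
    table = pd.DataFrame([pig_dyadic_traits(ev, pig) for pig in pigs])
    means = table.mean(axis=0, skipna=False)
    means.name = pen_id
    return means


def dyadic_trait_table(events: pd.DataFrame, roster: pd.DataFrame) -> pd.DataFrame:
    """Pen-level dyadic trait means: one row per pen.

    Vectorised equivalent of averaging :func:`pig_dyadic_traits` over
    each pen's roster (zero-activity pigs included in the divisor).
    """
    pigs = roster[["pig_id", "pen_id"]]
    unknown = (set(events["initiator"]) | set(events["receiver"])) - set(pigs["pig_id"])
    if unknown:
        raise ValueError(f"events reference pigs not in roster: {sorted(unknown)[:5]}")
    # one participation row per (event, pig in event)
    roles = []
    for role, pig_col in (("initiator", "initiator"), ("receiver", "receiver")):
        part = events[[pig_col, "behaviour", "duration", "bite_count"]].rename(
            columns={pig_col: "pig_id"}
        )
        part["role"] = role
        roles.append(part)
    part = pd.concat(roles, ignore_index=True)

    per_pig = pd.DataFrame(index=pigs["pig_id"])
    grp = part.groupby("pig_id")
    per_pig["_bout_dur"] = grp["duration"].sum()
    per_pig["_bouts"] = grp.size()

    fights = part[part["behaviour"] == "fight"]
    fgrp = fights.groupby("pig_id")
    per_pig["total_fight_duration"] = fgrp["duration"].sum()
    per_pig["n_fights"] = fgrp.size()
    injurious_dur = fights["duration"].where(
        fights["bite_count"] / fights["duration"] >= INJURIOUS_BITE_RATE, 0.0
    )
    per_pig["_inj_dur"] = injurious_dur.groupby(fights["pig_id"]).sum()
    per_pig["_missing_bites"] = (
        fights["bite_count"].isna().groupby(fights["pig_id"]).any()
    )

    bullies = part[part["behaviour"] == "bully"]
    for role, name in (("initiator", "bully_given_duration"), ("receiver", "bully_received_duration")):
        sub = bullies[bullies["role"] == role]
        per_pig[name] = sub.groupby("pig_id")["duration"].sum()

    per_pig = per_pig.fillna(0.0)
    with np.errstate(invalid="ignore"):
        per_pig["mean_duration_fight_bully"] = np.where(
            per_pig["_bouts"] > 0, per_pig["_bout_dur"] / per_pig["_bouts"], 0.0
        )
        per_pig["prop_injurious_fight_time"] = np.where(
            per_pig["total_fight_duration"] > 0,
            per_pig["_inj_dur"] / per_pig["total_fight_duration"],
            0.0,
        )
    missing = per_pig["_missing_bites"].astype(bool) & (per_pig["total_fight_duration"] > 0)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} pig(s) have fights without bite counts; "
            "their injurious-fighting proportion is reported as missing",
            MissingBiteCountWarning,
            stacklevel=2,
        )
        per_pig.loc[missing, "prop_injurious_fight_time"] = np.nan

    per_pig = per_pig[TRAIT_COLUMNS].reset_index()
    merged = pigs.merge(per_pig, on="pig_id", how="left")
    grouped = merged.groupby("pen_id", sort=False)
    means = grouped[TRAIT_COLUMNS].mean().reset_index()
    # a pen with any undefined pig-level proportion has an undefined mean
    undefined = grouped["prop_injurious_fight_time"].agg(lambda s: s.isna().any())
    means.loc[undefined.to_numpy(), "prop_injurious_fight_time"] = np.nan
    return means
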