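"""End-to-end orchestration: events -> networks -> traits -> models -> permutations.

``run_pipeline`` executes the full analysis for a configured set of
lesion responses (timepoint x body region): pen outcomes and covariates,
network and dyadic trait tables, the partial mixed model, stepwise trait
selection on its residuals, the full model for the selected traits, the
permutation verification of each selected network trait, and the
Spearman correlation matrix of all candidate traits.  Every artifact is
written under the configured output directory and also returned in a
report bundle.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .metrics import pen_trait_table
from .models import (
    DEFAULT_SLENTRY,
    DEFAULT_SLSTAY,
    fit_full_model,
    fit_partial_model,
    pen_covariate_table,
    pen_lesion_outcomes,
    spearman_matrix,
    stepwise_select,
)
from .permutation import DEFAULT_N_PERM, coefficient_histogram_report, permutation_test
from .traits import dyadic_trait_table

__all__ = ["PipelineConfig", "run_pipeline", "candidate_trait_table"]

DEFAULT_RESPONSES = (
    ("24h", "anterior"), ("24h", "central"), ("24h", "posterior"), ("24h", "total"),
    ("3wk", "anterior"), ("3wk", "central"), ("3wk", "posterior"), ("3wk", "total"),
)

NETWORK_TRAIT_COLUMNS = (
    "degree_centralisation",
    "in_degree_centralisation",
    "out_degree_centralisation",
    "betweenness_centralisation",
    "eigenvector_centralisation",
    "closeness_centralisation",
    "largest_clique_size",
)


@dataclass
class PipelineConfig:
    roster_path: str | Path = "roster.csv"
    events_path: str | Path = "events.csv"
    lesions_path: str | Path = "lesions.csv"
    out_dir: str | Path = "agonet_out"
    behaviours: tuple[str, ...] = ("fight", "bully", "combined")
    responses: tuple[tuple[str, str], ...] = DEFAULT_RESPONSES
    slentry: float = DEFAULT_SLENTRY
    slstay: float = DEFAULT_SLSTAY
    n_perm: int = DEFAULT_N_PERM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def candidate_trait_table(
    roster: pd.DataFrame,
    events: pd.DataFrame,
    behaviours: tuple[str, ...] = ("fight", "bully", "combined"),
) -> tuple[pd.DataFrame, pd.DataFrame, list[str], list[str]]:
    """Wide per-pen candidate predictors: network traits and dyadic means.

    Network trait columns are prefixed by behaviour type
    (``fight_betweenness_centralisation`` etc.); dyadic means keep their
    own names.  Returns (candidates, tidy network trait table,
    network trait names, dyadic trait names).
    """
    net_tidy = pen_trait_table(events, roster, behaviours)
    wide = None
    network_names: list[str] = []
    for behaviour in behaviours:
        sub = net_tidy[net_tidy["behaviour"] == behaviour]
        cols = [c for c in NETWORK_TRAIT_COLUMNS if c in sub.columns and sub[c].notna().all()]
        renamed = sub[["pen_id", *cols]].rename(
            columns={c: f"{behaviour}_{c}" for c in cols}
        )
        network_names += [f"{behaviour}_{c}" for c in cols]
        wide = renamed if wide is None else wide.merge(renamed, on="pen_id")
    dyadic = dyadic_trait_table(events, roster)
    dyadic_names = [c for c in dyadic.columns if c != "pen_id"]
    candidates = wide.merge(dyadic, on="pen_id")
    return candidates, net_tidy, network_names, dyadic_names


def run_pipeline(config: PipelineConfig, inputs=None) -> dict:
    """Run the whole analysis; returns (and writes) the report bundle.

    ``inputs`` may carry pre-loaded ``(roster, events, lesions)`` frames;
    otherwise the configured paths are read.  The stepwise stage is run
    separately for network traits and for dyadic traits, mirroring the
    two candidate families, and each selected network trait is verified
    by permutation.
    """
    from .io import read_events, read_lesions, read_roster  # cycle-free local import

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if inputs is None:
        roster = read_roster(config.roster_path)
        events = read_events(config.events_path)
        lesions = read_lesions(config.lesions_path)
    else:
        roster, events, lesions = inputs

    outcomes = pen_lesion_outcomes(lesions, roster)
    covariates = pen_covariate_table(roster, events)
    candidates, net_tidy, network_names, dyadic_names = candidate_trait_table(
        roster, events, config.behaviours
    )

    net_tidy.to_csv(out_dir / "network_traits.csv", index=False)
    candidates.to_csv(out_dir / "pen_candidate_traits.csv", index=False)
    outcomes.to_csv(out_dir / "pen_outcomes.csv", index=False)

    corr = spearman_matrix(candidates.drop(columns=["pen_id"]))
    corr.rho.to_csv(out_dir / "spearman_rho.csv")
    corr.p.to_csv(out_dir / "spearman_p.csv")

    bundle: dict = {
        "version": __version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "slentry": config.slentry,
        "slstay": config.slstay,
        "responses": {},
    }
    cand_indexed = candidates.set_index("pen_id")

    for timepoint, region in config.responses:
        key = f"{timepoint}_{region}"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            partial = fit_partial_model(outcomes, covariates, timepoint, region)
        residuals = partial.residuals("conditional")
        entry: dict = {"partial": partial.summary_dict()}

        for family, names in (("network", network_names), ("dyadic", dyadic_names)):
            fam_cands = cand_indexed[names].dropna(axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                step = stepwise_select(
                    residuals, fam_cands, slentry=config.slentry, slstay=config.slstay
                )
            fam_entry: dict = {
                "selected": step.selected,
                "steps": step.steps,
                "skipped_collinear": step.skipped_collinear,
            }
            if step.selected:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    full = fit_full_model(
                        outcomes, covariates, candidates, step.selected, timepoint, region
                    )
                fam_entry["full"] = full.summary_dict()
                if family == "network":
                    fam_entry["permutations"] = {}
                    for trait in step.selected:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            perm = permutation_test(
                                outcomes,
                                covariates,
                                candidates,
                                trait,
                                selected=step.selected,
                                timepoint=timepoint,
                                region=region,
                                n_perm=config.n_perm,
                                seed=config.seed,
                            )
                        report = coefficient_histogram_report(
                            perm, path=out_dir / f"permutation_{key}_{trait}.png"
                        )
                        fam_entry["permutations"][trait] = report
            entry[family] = fam_entry
        bundle["responses"][key] = entry

    with open(out_dir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2)
    return bundle
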