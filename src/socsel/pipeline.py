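"""End-to-end orchestration: detections to selection decomposition.

``run_all`` chains every stage on a synthetic winter: simulate
arrivals, settlement and detections; detect gathering events; build the
group-by-individual matrix and simple-ratio-index network; measure
weighted assortativity with its permutation null; standardize arrival
time, compute the social environment, generate territory outcomes under
the configured gradients, refit the gradients and decompose total
selection; run the breeding-geography tests and competition index; and
partition brood/year variance. Stages share one master seed fanned out
to per-stage streams, and every report is plain JSON/CSV.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assortativity import permute_datastream, weighted_assortativity
from .brood import variance_components
from .gathering import WeekCalendar, build_gbi, detect_events, first_detection_week
from .network import simple_ratio_index, social_environment
from .selection import decompose, fit_gradients, standardize
from .simulate import (
    SimulationConfig,
    generate_arrivals,
    generate_breeding_locations,
    generate_detections,
    generate_fitness,
    make_nestboxes,
)
from .spatial import (
    build_sitemap,
    competition_index,
    dyad_distance_test,
    visit_proportions,
    weight_distance_slope,
)

__all__ = ["run_all", "percentage", "config_hash", "summary_row"]


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Share of a count as a percentage, rounded for reporting."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def config_hash(config: SimulationConfig) -> str:
    text = yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def summary_row(
    year: str,
    n_juveniles: int,
    n_total: int,
    n_on_territory: int,
    gradients,
    decomposition,
) -> dict:
    """One line of the selection summary table."""
    return {
        "year": year,
        "n_juveniles": n_juveniles,
        "pct_juveniles": percentage(n_juveniles, n_total),
        "n_on_territory": n_on_territory,
        "beta_N": gradients.beta_N,
        "se_N": gradients.se_N,
        "p_N": gradients.p_N,
        "beta_S": gradients.beta_S,
        "se_S": gradients.se_S,
        "p_S": gradients.p_S,
        "C_I": decomposition.C_I,
        "term_nonsocial": decomposition.term_nonsocial,
        "term_social": decomposition.term_social,
        "s_total": decomposition.s_total,
    }


def run_all(
    config: SimulationConfig,
    out_dir: Optional[str] = None,
    n_perm: int = 200,
    n_rand: int = 1000,
    n_nestboxes: int = 1077,
    event_method: str = "gap",
    max_gap_s: float = 600.0,
    with_spatial: bool = True,
    with_brood: bool = True,
    competition_boxes: str = "all",
    juveniles_only: bool = True,
    progress: bool = False,
) -> dict:
    """Run every analysis stage on one synthetic winter.

    Returns a dict of stage results; when ``out_dir`` is given, each
    stage also writes a JSON report plus a run manifest with the seed,
    config hash and file digests so the run can be reproduced and
    audited.
    """
    from . import io as sio

    t0 = time.time()
    report: dict = {"config": dataclasses.asdict(config)}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def log(msg):
        if progress:
            import sys

            print(f"[socsel +{time.time() - t0:6.1f}s] {msg}", file=sys.stderr)

    # --- simulate ---------------------------------------------------
    log("simulating population and detections")
    population = generate_arrivals(config)
    synth = generate_detections(population, config)
    population = synth.population
    report["simulate"] = {
        "n_individuals": len(population),
        "n_true_events": len(synth.events),
        "n_detections": len(synth.detections),
    }

    # --- gathering events -------------------------------------------
    log("detecting gathering events")
    events = detect_events(synth.detections, method=event_method, max_gap_s=max_gap_s)
    detected_ids = sorted(set().union(*(ev.members for ev in events))) if events else []
    gbi = build_gbi(events, detected_ids, sparse_output=len(detected_ids) > 2000)
    report["gathering"] = {
        "n_events": gbi.n_events,
        "n_individuals_detected": gbi.n_individuals,
        "mean_event_size": float(gbi.event_sizes().mean()) if gbi.n_events else 0.0,
    }

    # --- network ----------------------------------------------------
    log("building association network")
    net = simple_ratio_index(gbi)
    report["network"] = {"n_nodes": net.n, "n_edges": int(len(net.edges()[0])), "density": net.density()}

    # --- arrival trait ----------------------------------------------
    calendar = WeekCalendar(start=pd.Timestamp(config.season_start), n_weeks=config.n_weeks)
    observed_week = first_detection_week(synth.detections, calendar)
    trait = observed_week.reindex(net.roster)
    std = standardize(trait.to_numpy())
    z = pd.Series(std.z, index=net.roster)

    # --- assortativity ----------------------------------------------
    log("assortativity and permutation null")
    assort = weighted_assortativity(net, trait, with_se=True)
    stat = lambda g: weighted_assortativity(simple_ratio_index(g), trait).r_hat
    # sampling-day strata: swaps preserve each bird's temporal presence
    # (and hence arrival censoring) but may cross feeders, so the null
    # breaks spatial trait clustering while conserving margins
    strata = [pd.Timestamp(ev.start).normalize() for ev in events]
    perm = permute_datastream(
        gbi,
        stat,
        n_perm=n_perm,
        n_swaps=20,
        strata=strata,
        seed=int(config.rng(3).integers(2**31)),
    )
    report["assortativity"] = {
        "r_hat": assort.r_hat,
        "se": assort.se,
        "n_edges": assort.n_edges,
        "p_value": perm.p_value,
        "n_perm": perm.n_perm,
    }

    # --- selection --------------------------------------------------
    log("selection gradients")
    env = social_environment(net, z)
    zbar = pd.Series(env.zbar, index=net.roster)
    pop = population.set_index("individual_id")
    z_pop = z.reindex(pop.index).to_numpy()
    zbar_pop = zbar.reindex(pop.index).to_numpy()
    pop_fit = generate_fitness(
        pop.reset_index(), z_pop, zbar_pop, config
    ).set_index("individual_id")

    if juveniles_only:
        fit_mask = (pop_fit["age_class"] == "juvenile").to_numpy()
    else:
        fit_mask = np.ones(len(pop_fit), dtype=bool)
    grads = fit_gradients(
        pop_fit["bred"].to_numpy()[fit_mask], z_pop[fit_mask], zbar_pop[fit_mask]
    )
    decomp = decompose(std.P, assort.r_hat, grads.beta_N, grads.beta_S)
    n_juv = int((pop_fit["age_class"] == "juvenile").sum())
    year_label = str(pd.Timestamp(config.season_start).year)
    report["selection"] = {
        "gradients": dataclasses.asdict(grads),
        "decomposition": {
            "P": decomp.P,
            "C_I": decomp.C_I,
            "term_nonsocial": decomp.term_nonsocial,
            "term_social": decomp.term_social,
            "s_total": decomp.s_total,
        },
        "true_beta_N": config.beta_N,
        "true_beta_S": config.beta_S,
    }
    report["summary"] = summary_row(
        year_label,
        n_juv,
        len(pop_fit),
        int(pop_fit.loc[fit_mask, "bred"].sum()),
        grads,
        decomp,
    )

    # --- spatial ----------------------------------------------------
    if with_spatial:
        log("breeding geography and competition")
        boxes = make_nestboxes(n_nestboxes, config)
        pop_boxed = generate_breeding_locations(
            pop_fit.reset_index(), boxes, synth.feeders
        )
        sitemap = build_sitemap(synth.feeders, boxes)
        breeders = pop_boxed.loc[pop_boxed["bred"] == 1]
        breeding_xy = (
            boxes.set_index("box_id")
            .loc[breeders["breeding_box"], ["x", "y"]]
            .set_axis(breeders["individual_id"])
        )
        dyads = dyad_distance_test(net, breeding_xy)
        slope = weight_distance_slope(
            net, breeding_xy, boxes, n_rand=n_rand,
            seed=int(config.rng(4).integers(2**31)),
        )
        props = visit_proportions(synth.detections)
        # all boxes as the divisor: with sparse synthetic breeding, the
        # used-boxes-only variant can leave feeders with birds but no
        # box, where competition is undefined
        if competition_boxes == "used":
            used = breeders["breeding_box"].tolist()
        else:
            used = boxes["box_id"].tolist()
        comp = competition_index(props, sitemap, used)
        report["spatial"] = {
            "dyad_distance": dataclasses.asdict(dyads),
            "weight_distance": {
                "slope": slope.slope,
                "se": slope.se,
                "p_rand": slope.p_rand,
                "n_dyads": slope.n_dyads,
            },
            "competition": {
                "mean": float(comp.individual_competition.mean()),
                "global_ratio": len(pop_fit) / n_nestboxes,
            },
        }
    else:
        report["spatial"] = None

    # --- brood ------------------------------------------------------
    if with_brood:
        log("brood variance partitioning")
        from .simulate import generate_multiyear_arrivals

        multi = generate_multiyear_arrivals(
            brood_var_frac=config.brood_var_frac,
            year_var_frac=config.year_var_frac,
            total_sd=config.late_arrival_sd,
            mean_week=config.late_arrival_mean,
            n_weeks=config.n_weeks,
            seed=int(config.rng(6).integers(2**31)),
        )
        vc = variance_components(
            multi["arrival_week"], multi["brood_id"], multi["year"]
        )
        report["brood"] = {
            "frac_brood": vc.frac_brood,
            "frac_year": vc.frac_year,
            "var_brood": vc.var_brood,
            "var_year": vc.var_year,
            "var_resid": vc.var_resid,
        }
    else:
        report["brood"] = None

    # --- manifest / outputs -----------------------------------------
    if out is not None:
        stages = {}
        for name in ("simulate", "gathering", "network", "assortativity", "selection", "spatial", "brood", "summary"):
            path = out / f"{name}.json"
            sio.write_json({name: report[name]}, path)
            stages[name] = sio.file_digest(path)
        manifest = {
            "package_version": __version__,
            "seed": config.seed,
            "config_hash": config_hash(config),
            "stages": stages,
        }
        sio.write_json(manifest, out / "manifest.json")
        report["manifest"] = manifest
    log("done")
    return report
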