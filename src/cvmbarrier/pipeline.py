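"""End-to-end orchestration: simulate -> MSD -> mobility -> pore size ->
CST -> cohort statistics -> report.

A single :class:`RunConfig` drives every stage.  All randomness flows
from one seeded root generator through per-stage substreams, so a
config plus seed fully determines every output byte.  Stage outputs are
written as CSV/TSV beside a JSON provenance block.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate.trajectories import OpticsConfig, PopulationSpec, simulate_sample
from .simulate.cohort import CohortConfig, SyntheticCohort, simulate_cohort
from .msd import msd_at_one_second, msd_table
from .mobility import LogMSDMixture, sample_mobility_table
from .pore_size import (PoreModelConditions, obstruction_hindrance,
                        stokes_einstein_d0, sample_pore_size,
                        pore_size_table)
from .cst import CSTClassifier, carry_forward_cst, \
    participant_cst_mobility_average
from .cohort_stats import (ContingencyTable, apply_exclusions,
                           contingency_stats, welch_t, anova_tukey,
                           slope_regression)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "load_config",
           "cst_distribution_by_outcome", "demographics_table",
           "simulate_sample_trajectories"]

#: Probe name -> diameter in nm.
PROBE_DIAMETERS = {"MPP100": 100.0, "MPP200": 200.0, "MPP500": 500.0}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str | None = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    conditions: PoreModelConditions = field(default_factory=PoreModelConditions)
    n_particles_per_sample: int = 60
    trapped_diffusivity: float = 1e-4   # um^2/s, slow-diffusion trapped model
    trapped_alpha: float = 1.0          # < 1 switches trapped to fBm
    write_trajectories: bool = False
    tau: float = 1.0                    # s


def load_config(path, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a declarative YAML file.

    Top-level keys mirror the RunConfig fields; the nested ``cohort``,
    ``optics`` and ``conditions`` mappings are passed to their config
    classes.  Keyword ``overrides`` (e.g. from CLI flags) win over the
    file.
    """
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.update(overrides)
    kwargs = {}
    if "cohort" in raw:
        kwargs["cohort"] = CohortConfig(**raw.pop("cohort"))
    if "optics" in raw:
        opt = raw.pop("optics")
        if "image_shape" in opt:
            opt["image_shape"] = tuple(opt["image_shape"])
        kwargs["optics"] = OpticsConfig(**opt)
    if "conditions" in raw:
        kwargs["conditions"] = PoreModelConditions(**raw.pop("conditions"))
    kwargs.update(raw)
    return RunConfig(**kwargs)


@dataclass
class ReportBundle:
    metadata: pd.DataFrame
    mobility: pd.DataFrame
    pore_sizes: pd.DataFrame
    cst_assignments: pd.DataFrame
    cst_by_outcome: pd.DataFrame
    participant_mobility: pd.DataFrame
    mobility_vs_week: pd.DataFrame
    group_tests: dict
    exclusion_log: dict
    provenance: dict


def simulate_sample_trajectories(cohort: SyntheticCohort,
                                 config: RunConfig,
                                 rng: np.random.Generator) -> pd.DataFrame:
    """Simulate trajectories for every (sample, probe) and reduce them to
    per-particle MSD records at ``config.tau``.

    Mobile particles diffuse at the rate the obstruction model predicts
    for the sample's generating pore size; trapped particles use the
    configured slow/subdiffusive dynamics.
    """
    cond = config.conditions
    pore = cohort.true_pore_nm.set_index("sample_id")["pore_nm"]
    rows = []
    for (sid, probe), grp in cohort.true_mobility.groupby(
            ["sample_id", "probe"], sort=True):
        f_mobile = float(grp["mobile_fraction"].iloc[0])
        diameter = PROBE_DIAMETERS[probe]
        d0 = stokes_einstein_d0(diameter, cond.temperature, cond.viscosity)
        d_mobile = d0 * obstruction_hindrance(float(pore[sid]), diameter,
                                              cond.d_fiber)
        pops = [
            PopulationSpec("trapped", 1.0 - f_mobile,
                           config.trapped_diffusivity, config.trapped_alpha),
            PopulationSpec("mobile", f_mobile, d_mobile),
        ]
        trajset = simulate_sample(pops, config.n_particles_per_sample,
                                  config.optics, seed=rng)
        records = msd_at_one_second(trajset, tau=config.tau)
        rows.append(msd_table(records, sample_id=sid, probe=probe))
    if not rows:
        return pd.DataFrame(columns=["sample_id", "probe", "particle_id",
                                     "msd_um2_tau1", "log10_msd", "n_pairs"])
    return pd.concat(rows, ignore_index=True)


def cst_distribution_by_outcome(assignments: pd.DataFrame,
                                outcomes: pd.DataFrame) -> pd.DataFrame:
    """Percentage of samples in each CST per delivery-outcome group.

    ``assignments`` maps sample_id -> cst; ``outcomes`` maps sample_id
    -> outcome.  Percentages sum to 100 within each group.
    """
    merged = assignments[["sample_id", "cst"]].merge(
        outcomes[["sample_id", "outcome"]], on="sample_id")
    rows = []
    for outcome, grp in merged.groupby("outcome", sort=True):
        n = len(grp)
        if n == 0:
            logger.warning("outcome group %r is empty; omitted", outcome)
            continue
        counts = grp["cst"].value_counts()
        for cst in ("I", "II", "III", "IV", "V"):
            rows.append(dict(outcome=outcome, cst=cst,
                             n=int(counts.get(cst, 0)),
                             percent=100.0 * counts.get(cst, 0) / n))
    return pd.DataFrame(rows)


def demographics_table(participants: pd.DataFrame,
                       attributes: list[str] | None = None,
                       outcome_col: str = "outcome",
                       case_label: str = "preterm") -> pd.DataFrame:
    """Count/percentage demographics table with RR/OR per attribute.

    For each boolean attribute column, cells are formatted
    ``"count (percent)"`` with the percentage rounded to the nearest
    integer within each outcome-group denominator, and the exposure-by-
    outcome 2x2 table yields RR, OR and Fisher p.
    """
    if attributes is None:
        attributes = [c for c in participants.columns
                      if participants[c].dtype == bool]
    is_case = participants[outcome_col] == case_label
    n_total, n_case = len(participants), int(is_case.sum())
    n_noncase = n_total - n_case
    rows = []
    for attr in attributes:
        if attr not in participants.columns:
            logger.warning("unknown attribute column %r skipped", attr)
            continue
        flag = participants[attr].astype(bool)
        a = int((flag & is_case).sum())
        b = int((flag & ~is_case).sum())
        c = int((~flag & is_case).sum())
        d = int((~flag & ~is_case).sum())
        res = contingency_stats(ContingencyTable(a, b, c, d))

        def cell(count, denom):
            pct = round(100.0 * count / denom) if denom else 0
            return f"{count} ({pct})"

        rows.append(dict(
            label=attr,
            total=cell(a + b, n_total),
            term=cell(b, n_noncase),
            preterm=cell(a, n_case),
            rr=res.rr, or_=res.or_,
            rr_ci_low=res.rr_ci[0], rr_ci_high=res.rr_ci[1],
            or_ci_low=res.or_ci[0], or_ci_high=res.or_ci[1],
            fisher_p=res.fisher_p))
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, pd.DataFrame):
            return o.to_dict()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, tuple):
            return list(o)
        return str(o)
    blob = json.dumps(asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig | None = None,
                 msd_records: pd.DataFrame | None = None) -> ReportBundle:
    """Execute the full analysis and return a :class:`ReportBundle`.

    Stages run in dependency order: cohort simulation, per-sample
    trajectory simulation and MSD reduction (skipped when
    ``msd_records`` supplies a precomputed per-particle table, e.g. from
    video tracking), mobility mixture fits, pore-size inversion, CST
    assignment with carry-forward, and the statistics layer.  When
    ``config.outdir`` is set, every stage's table is written there as
    CSV along with a JSON provenance block.
    """
    config = config or RunConfig()
    root = np.random.SeedSequence(config.seed)
    ss_cohort, ss_traj = root.spawn(2)

    # stage 1: cohort ---------------------------------------------------
    cohort_cfg = config.cohort
    cohort_cfg.seed = ss_cohort.generate_state(1)[0]
    cohort = simulate_cohort(cohort_cfg)
    logger.info("cohort: %d participants, %d samples",
                len(cohort.participants), len(cohort.metadata))

    # stage 2: exclusions ----------------------------------------------
    retained, exclusion_log = apply_exclusions(cohort.metadata)
    keep_ids = set(retained["sample_id"])

    # stage 3: particle tracking analog + MSD --------------------------
    if msd_records is None:
        rng = np.random.default_rng(ss_traj)
        msd_records = simulate_sample_trajectories(cohort, config, rng)
    msd_records = msd_records[msd_records["sample_id"].isin(keep_ids)]

    # stage 4: mobility mixture fits -----------------------------------
    mobility = sample_mobility_table(msd_records, estimator=LogMSDMixture())

    # stage 5: pore size from MPP ensemble-average MSDs ----------------
    estimates = []
    for sid, grp in msd_records.groupby("sample_id", sort=True):
        msd_by_probe = {
            PROBE_DIAMETERS[probe]: float(g["msd_um2_tau1"].mean())
            for probe, g in grp.groupby("probe")
            if probe in PROBE_DIAMETERS}
        if msd_by_probe:
            estimates.append(sample_pore_size(msd_by_probe, sample_id=sid,
                                              conditions=config.conditions))
    pore_sizes = pore_size_table(estimates)

    # stage 6: CST assignment ------------------------------------------
    comp = cohort.compositions.loc[
        [s for s in cohort.compositions.index if s in keep_ids]]
    clf = CSTClassifier(n_clusters=5).fit(comp)
    assignments = clf.assignments_frame()
    assignments = assignments.merge(
        retained[["sample_id", "participant_id", "week", "outcome",
                  "delivery_week"]], on="sample_id")

    # carry-forward bookkeeping per participant
    timelines = []
    for pid, grp in assignments.groupby("participant_id", sort=True):
        tl = carry_forward_cst(grp[["week", "cst"]],
                               float(grp["delivery_week"].iloc[0]))
        tl.insert(0, "participant_id", pid)
        timelines.append(tl)
    timeline = pd.concat(timelines, ignore_index=True) if timelines \
        else pd.DataFrame()

    # stage 7: statistics ----------------------------------------------
    cst_by_outcome = cst_distribution_by_outcome(assignments, retained)
    participant_mobility = participant_cst_mobility_average(
        mobility, assignments)

    # mobile fraction and pore size: CST I vs CST IV, ANOVA across CSTs
    per_sample_mob = (mobility.groupby("sample_id")["mobile_fraction"]
                      .mean().rename("mobile_fraction").reset_index())
    merged_mob = per_sample_mob.merge(
        assignments[["sample_id", "cst"]], on="sample_id")
    merged_xi = pore_sizes.merge(
        assignments[["sample_id", "cst"]], on="sample_id").dropna(
        subset=["xi_mean_nm"])
    group_tests: dict = {}
    mob_groups = {c: g["mobile_fraction"].to_numpy()
                  for c, g in merged_mob.groupby("cst") if len(g) >= 2}
    xi_groups = {c: g["xi_mean_nm"].to_numpy()
                 for c, g in merged_xi.groupby("cst") if len(g) >= 2}
    if {"I", "IV"} <= set(mob_groups):
        t, df, p = welch_t(mob_groups["I"], mob_groups["IV"])
        group_tests["mobility_I_vs_IV"] = dict(
            t=t, df=df, p=p,
            mean_I=float(np.mean(mob_groups["I"])),
            mean_IV=float(np.mean(mob_groups["IV"])))
    if {"I", "IV"} <= set(xi_groups):
        t, df, p = welch_t(xi_groups["I"], xi_groups["IV"])
        group_tests["pore_I_vs_IV"] = dict(
            t=t, df=df, p=p,
            mean_I=float(np.mean(xi_groups["I"])),
            mean_IV=float(np.mean(xi_groups["IV"])))
    if len(mob_groups) >= 3:
        F, p, pairwise = anova_tukey(mob_groups)
        group_tests["mobility_anova"] = dict(
            F=F, p=p, pairwise=pairwise.to_dict("records"))

    # mobility vs weeks of pregnancy, per probe
    reg_rows = []
    mob_week = mobility.merge(retained[["sample_id", "week"]], on="sample_id")
    for probe, grp in mob_week.dropna(subset=["mobile_fraction"]).groupby(
            "probe", sort=True):
        if len(grp) >= 3 and np.ptp(grp["week"].to_numpy()) > 0:
            slope, r2, p = slope_regression(grp["week"], grp["mobile_fraction"])
            reg_rows.append(dict(probe=probe, slope=slope, r_squared=r2,
                                 p_value=p, n=len(grp)))
    mobility_vs_week = pd.DataFrame(reg_rows)

    provenance = dict(package="cvmbarrier", version=__version__,
                      seed=config.seed, config_hash=_config_hash(config),
                      n_participants=int(len(cohort.participants)),
                      n_samples=int(len(cohort.metadata)),
                      n_retained=exclusion_log["retained"])

    bundle = ReportBundle(
        metadata=cohort.metadata, mobility=mobility, pore_sizes=pore_sizes,
        cst_assignments=assignments, cst_by_outcome=cst_by_outcome,
        participant_mobility=participant_mobility,
        mobility_vs_week=mobility_vs_week, group_tests=group_tests,
        exclusion_log=exclusion_log, provenance=provenance)

    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.metadata.to_csv(out / "metadata.csv", index=False)
        cohort.compositions.to_csv(out / "compositions.tsv", sep="\t",
                                   index_label="sample_id")
        if config.write_trajectories:
            msd_records.to_csv(out / "msd_records.csv", index=False)
        mobility.to_csv(out / "mobility.csv", index=False)
        pore_sizes.to_csv(out / "pore_sizes.csv", index=False)
        assignments.to_csv(out / "cst_assignments.csv", index=False)
        if len(timeline):
            timeline.to_csv(out / "cst_timeline.csv", index=False)
        cst_by_outcome.to_csv(out / "cst_by_outcome.csv", index=False)
        participant_mobility.to_csv(out / "participant_mobility.csv",
                                    index=False)
        mobility_vs_week.to_csv(out / "mobility_vs_week.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(dict(provenance=provenance, group_tests=group_tests,
                           exclusions=exclusion_log), fh, indent=2,
                      default=float)
    return bundle
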