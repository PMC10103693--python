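"""Longitudinal synthetic pregnancy cohort.

Each participant is enrolled in early-mid pregnancy, sampled roughly
every ``visit_interval`` weeks, and carries a vaginal community state
type (CST) that evolves between visits as a first-order Markov chain.
Each visit yields a microbiome composition vector, per-probe mobile
fractions drawn around per-CST means, sample-quality exclusion flags,
and the participant eventually delivers at term or preterm with a
CST-dependent risk.

Ground truth (CST path, generating mobile fractions, generating pore
size) is retained so downstream recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .microbiome import CST_LABELS, simulate_composition_table

__all__ = ["CohortConfig", "SyntheticCohort", "simulate_cohort",
           "DEFAULT_TRANSITIONS", "DEFAULT_MOBILITY_MEANS",
           "DEFAULT_PORE_NM", "DEFAULT_PRETERM_RISK", "MPP_PROBES"]

#: Mucus-penetrating probe names used for pore-size work (diameter in nm).
MPP_PROBES = ("MPP100", "MPP200", "MPP500")

#: First-order Markov transitions between CSTs per visit.  Diagonal-heavy
#: (states are sticky month to month); the largest off-diagonal moves are
#: III->I and III->IV, the transitions most often seen in pregnancy
#: cohorts.
DEFAULT_TRANSITIONS = pd.DataFrame(
    [
        # to:   I      II     III    IV     V
        [0.88, 0.01, 0.06, 0.04, 0.01],   # from I
        [0.05, 0.82, 0.06, 0.05, 0.02],   # from II
        [0.12, 0.01, 0.72, 0.13, 0.02],   # from III
        [0.04, 0.01, 0.08, 0.85, 0.02],   # from IV
        [0.04, 0.02, 0.06, 0.04, 0.84],   # from V
    ],
    index=list(CST_LABELS), columns=list(CST_LABELS),
)

#: Mean mobile fraction per CST for each mucus-penetrating probe.
#: L. crispatus-dominated mucus (CST I) traps most; polymicrobial (IV)
#: and L. gasseri (II) mucus trap least; 500 nm probes are sterically
#: hindered more than 100/200 nm at every CST.
DEFAULT_MOBILITY_MEANS = {
    "I":   {"MPP100": 0.725, "MPP200": 0.628, "MPP500": 0.526},
    "II":  {"MPP100": 0.937, "MPP200": 0.974, "MPP500": 0.877},
    "III": {"MPP100": 0.830, "MPP200": 0.800, "MPP500": 0.700},
    "IV":  {"MPP100": 0.871, "MPP200": 0.880, "MPP500": 0.800},
    "V":   {"MPP100": 0.800, "MPP200": 0.700, "MPP500": 0.620},
}

#: Generating effective pore size (nm) per CST; CST I mesh is tightest,
#: polymicrobial CST IV loosest, cohort-wide average near ~310 nm.
DEFAULT_PORE_NM = {"I": 240.0, "II": 380.0, "III": 330.0,
                   "IV": 420.0, "V": 300.0}

#: Probability of preterm delivery given the highest-risk CST occupied.
DEFAULT_PRETERM_RISK = {"I": 0.05, "II": 0.05, "III": 0.12,
                        "IV": 0.25, "V": 0.08}

#: Initial CST distribution (approximate cohort sample shares).
DEFAULT_INITIAL_CST = {"I": 0.29, "II": 0.04, "III": 0.32,
                       "IV": 0.28, "V": 0.07}


@dataclass
class CohortConfig:
    n_participants: int = 30
    visit_interval: float = 4.0               # weeks between samples
    cst_transition_matrix: pd.DataFrame = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial_cst_probs: dict = field(
        default_factory=lambda: dict(DEFAULT_INITIAL_CST))
    per_cst_mobility_means: dict = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_MOBILITY_MEANS.items()})
    mobility_sd: float = 0.06
    per_cst_pore_nm: dict = field(
        default_factory=lambda: dict(DEFAULT_PORE_NM))
    pore_sd_nm: float = 25.0
    preterm_risk_by_cst: dict = field(
        default_factory=lambda: dict(DEFAULT_PRETERM_RISK))
    exclusion_rates: dict = field(
        default_factory=lambda: {"blood": 0.05, "intercourse": 0.05})
    attrition_rate: float = 0.12              # P(participant stops sampling early)
    enrollment_week_range: tuple[float, float] = (8.0, 16.0)
    n_taxa: int = 12
    seed: int = 0

    def validate(self) -> None:
        tm = self.cst_transition_matrix
        if list(tm.index) != list(CST_LABELS) or list(tm.columns) != list(CST_LABELS):
            raise ValueError("transition matrix must be 5x5 over CSTs I-V")
        if not np.allclose(tm.to_numpy().sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(tm.to_numpy() < 0):
            raise ValueError("transition probabilities must be >= 0")
        for name, probs in (("preterm_risk_by_cst", self.preterm_risk_by_cst),
                            ("exclusion_rates", self.exclusion_rates),
                            ("initial_cst_probs", self.initial_cst_probs)):
            for k, v in probs.items():
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{name}[{k!r}] must be in [0,1], got {v}")
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")


@dataclass
class SyntheticCohort:
    """All generated tables plus ground truth for recovery tests."""

    metadata: pd.DataFrame       # one row per sample (visit)
    participants: pd.DataFrame   # one row per participant
    compositions: pd.DataFrame   # samples x taxa, rows sum to 1
    true_cst: pd.DataFrame       # sample_id -> generating CST
    true_mobility: pd.DataFrame  # sample_id, probe, mobile_fraction
    true_pore_nm: pd.DataFrame   # sample_id -> generating pore size
    config: CohortConfig


def simulate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a full longitudinal cohort from a :class:`CohortConfig`.

    The delivery outcome is Bernoulli with probability equal to the
    highest per-CST preterm risk among the CSTs the participant occupied
    before 27 weeks (exposure precedes the earliest possible delivery),
    so configured CST risk ratios are recovered by construction in
    expectation.
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = list(CST_LABELS)
    tm = config.cst_transition_matrix.loc[labels, labels].to_numpy()
    init_p = np.array([config.initial_cst_probs.get(c, 0.0) for c in labels])
    init_p = init_p / init_p.sum()

    meta_rows, part_rows, mob_rows, cst_rows, pore_rows = [], [], [], [], []
    all_cst_labels: list[str] = []
    all_sample_ids: list[str] = []

    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        week0 = rng.uniform(*config.enrollment_week_range)
        # visit grid through late pregnancy, capped at 37 weeks so the
        # CST exposure that sets risk coincides with the sampled visits
        weeks = np.arange(week0, 37.0, config.visit_interval)
        state = int(rng.choice(5, p=init_p))
        path = [state]
        for _ in range(len(weeks) - 1):
            state = int(rng.choice(5, p=tm[state]))
            path.append(state)
        cst_path = [labels[s] for s in path]

        # risk is set by the CSTs occupied before any possible delivery
        # (< 27 weeks), so exposure precedes outcome and is always
        # observed regardless of delivery timing
        risk_csts = {c for c, wk in zip(cst_path, weeks) if wk < 27.0}
        risk = max(config.preterm_risk_by_cst.get(c, 0.0) for c in risk_csts)
        preterm = bool(rng.random() < risk)
        delivery_week = (rng.uniform(27.0, 36.9) if preterm
                         else rng.uniform(37.0, 42.0))
        keep = weeks < delivery_week
        keep[0] = True  # enrollment sample always exists
        weeks, cst_path = weeks[keep], [c for c, k in zip(cst_path, keep) if k]

        # attrition: participant stops sampling before delivery
        if len(weeks) > 1 and rng.random() < config.attrition_rate:
            n_keep = int(rng.integers(1, len(weeks)))
            weeks, cst_path = weeks[:n_keep], cst_path[:n_keep]

        part_rows.append(dict(participant_id=pid,
                              enrollment_week=round(float(week0), 1),
                              delivery_week=round(float(delivery_week), 1),
                              outcome="preterm" if preterm else "term"))

        for v, (wk, cst) in enumerate(zip(weeks, cst_path)):
            sid = f"{pid}V{v:02d}"
            pore = max(float(rng.normal(config.per_cst_pore_nm[cst],
                                        config.pore_sd_nm)), 50.0)
            meta_rows.append(dict(
                participant_id=pid, sample_id=sid, week=round(float(wk), 1),
                probe_set=";".join(MPP_PROBES),
                blood_flag=bool(rng.random() < config.exclusion_rates["blood"]),
                intercourse_flag=bool(
                    rng.random() < config.exclusion_rates["intercourse"]),
                delivery_week=round(float(delivery_week), 1),
                outcome="preterm" if preterm else "term"))
            cst_rows.append(dict(sample_id=sid, participant_id=pid,
                                 week=round(float(wk), 1), cst=cst))
            pore_rows.append(dict(sample_id=sid, pore_nm=pore))
            for probe in MPP_PROBES:
                mu = config.per_cst_mobility_means[cst][probe]
                frac = float(np.clip(rng.normal(mu, config.mobility_sd), 0.0, 1.0))
                mob_rows.append(dict(sample_id=sid, probe=probe,
                                     mobile_fraction=frac))
            all_cst_labels.append(cst)
            all_sample_ids.append(sid)

    compositions = simulate_composition_table(
        all_cst_labels, n_taxa=config.n_taxa, seed=rng,
        sample_ids=all_sample_ids)

    return SyntheticCohort(
        metadata=pd.DataFrame(meta_rows),
        participants=pd.DataFrame(part_rows),
        compositions=compositions,
        true_cst=pd.DataFrame(cst_rows),
        true_mobility=pd.DataFrame(mob_rows),
        true_pore_nm=pd.DataFrame(pore_rows),
        config=config,
    )
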