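"""Seeded synthetic longitudinal EHR cohorts with planted, recoverable
structure.

The generator emulates the visit-level shape of ICU medication-recommendation
cohorts — visit counts, diagnosis/procedure multiplicities per visit — and
plants three kinds of recoverable signal:

* diagnosis→medication rules: once diagnosis d has appeared (rules are
  chronic by default — the trigger persists after first occurrence), the
  rule's medication fires with a configured probability at every
  subsequent visit; a rule may instead require d to have appeared in at
  least `min_count` distinct visits, modelling treatment escalation after
  repeated presentation — those medications are predictable only from the
  visit history, not from the latest visit alone;
* co-prescription clusters: once any cluster member is prescribed, the
  remaining members join with a configured probability (this is what makes
  the co-occurrence graph informative);
* contraindicated pairs: a DDI list emitted alongside the cohort, planted
  inside clusters so that co-occurrence pressure and safety pressure
  genuinely compete.

Visit counts are drawn as 2 + Poisson(mean_visits − 2): every patient has
at least the two visits the downstream filter requires, and the realized
mean matches the configured mean exactly in expectation.  Diagnoses use a
persistence mechanism (each previous-visit diagnosis recurs with a fixed
probability, topped up with fresh uniform draws), mirroring chronic-disease
code carry-over.  Codes are opaque strings ("D012", "P034", "M005") with no
ontology semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_io import CodeLevel, Cohort, Visit


@dataclass
class SynthConfig:
    n_patients: int = 1000
    n_diag: int = 200
    n_proc: int = 100
    n_med: int = 18
    mean_visits: float = 2.8169
    mean_diag: float = 9.3666
    mean_proc: float = 2.5492
    # (diag, med, firing prob[, min_count]) — min_count defaults to 1;
    # min_count k means the diagnosis must have appeared in >= k visits
    rule_table: list[tuple] = field(default_factory=list)
    copair_clusters: list[list[int]] = field(default_factory=list)
    copair_prob: float = 0.5
    ddi_pairs: list[tuple[int, int]] = field(default_factory=list)
    noise_rate: float = 0.01
    persistence: float = 0.5
    chronic_rules: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mean_visits < 2:
            raise ValueError("mean_visits must be >= 2 (patients need history)")
        if not (0 <= self.noise_rate <= 1 and 0 <= self.persistence <= 1
                and 0 <= self.copair_prob <= 1):
            raise ValueError("probabilities must lie in [0,1]")
        self.rule_table = [tuple(r) + (1,) * (4 - len(r))
                           for r in self.rule_table]
        for d, m, p, k in self.rule_table:
            if not (0 <= d < self.n_diag and 0 <= m < self.n_med
                    and 0 <= p <= 1 and k >= 1):
                raise ValueError(f"rule ({d},{m},{p},{k}) out of range")
        for cluster in self.copair_clusters:
            if any(not 0 <= m < self.n_med for m in cluster):
                raise ValueError(f"cluster {cluster} references unknown medication")
        for a, b in self.ddi_pairs:
            if not (0 <= a < self.n_med and 0 <= b < self.n_med) or a == b:
                raise ValueError(f"bad DDI pair ({a},{b})")


@dataclass
class GeneratorReport:
    mean_visits: float
    mean_diag: float
    mean_proc: float
    mean_med: float
    rule_conditional_freq: dict[tuple[int, int], float]
    ddi_coprescription_rate: float

    def as_dict(self) -> dict:
        return {
            "mean_visits": self.mean_visits,
            "mean_diag": self.mean_diag,
            "mean_proc": self.mean_proc,
            "mean_med": self.mean_med,
            "rule_conditional_freq": {f"{d}->{m}": v for (d, m), v
                                      in self.rule_conditional_freq.items()},
            "ddi_coprescription_rate": self.ddi_coprescription_rate,
        }


def _diag_code(i: int) -> str:
    return f"D{i:03d}"


def _proc_code(i: int) -> str:
    return f"P{i:03d}"


def med_code(i: int) -> str:
    return f"M{i:03d}"


def generate(config: SynthConfig) -> tuple[Cohort, GeneratorReport]:
    """Emit a cohort plus a report of the realized statistics.

    Deterministic for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    patients = []
    for pi in range(config.n_patients):
        n_visits = 2 + int(rng.poisson(config.mean_visits - 2.0))
        prev_diag: set[int] = set()
        diag_counts: dict[int, int] = {}
        visits = []
        for vi in range(n_visits):
            k_diag = max(1, int(rng.poisson(config.mean_diag)))
            carried = {d for d in prev_diag
                       if rng.random() < config.persistence}
            if len(carried) > k_diag:  # cap so the visit count stays Poisson
                carried = set(int(x) for x in rng.choice(
                    np.fromiter(carried, int, len(carried)), size=k_diag,
                    replace=False))
            need = k_diag - len(carried)
            diag = set(carried)
            if need > 0:
                pool = np.setdiff1d(np.arange(config.n_diag),
                                    np.fromiter(carried, int, len(carried)))
                diag |= set(int(x) for x in
                            rng.choice(pool, size=min(need, len(pool)),
                                       replace=False))
            prev_diag = diag

            k_proc = int(rng.poisson(config.mean_proc))
            proc = (set(int(x) for x in
                        rng.choice(config.n_proc,
                                   size=min(k_proc, config.n_proc),
                                   replace=False))
                    if k_proc else set())

            for d in diag:
                diag_counts[d] = diag_counts.get(d, 0) + 1
            meds: set[int] = set()
            for d, m, p, k in config.rule_table:
                triggered = (diag_counts.get(d, 0) >= k if config.chronic_rules
                             else d in diag and diag_counts.get(d, 0) >= k)
                if triggered and rng.random() < p:
                    meds.add(m)
            for cluster in config.copair_clusters:
                if meds & set(cluster):
                    for m in cluster:
                        if m not in meds and rng.random() < config.copair_prob:
                            meds.add(m)
            noise_mask = rng.random(config.n_med) < config.noise_rate
            meds |= set(int(x) for x in np.flatnonzero(noise_mask))

            visits.append(Visit(
                subject_id=f"S{pi:05d}", visit_index=vi,
                hadm_id=f"H{pi:05d}{vi:02d}",
                diagnoses=frozenset(_diag_code(d) for d in diag),
                procedures=frozenset(_proc_code(p) for p in proc),
                medications=frozenset(med_code(m) for m in meds)))
        patients.append((f"S{pi:05d}", visits))
    cohort = Cohort(patients=patients, level=CodeLevel.ATC04)
    return cohort, _report(cohort, config)


def _report(cohort: Cohort, config: SynthConfig) -> GeneratorReport:
    n_visits_per_patient = [len(v) for _, v in cohort.patients]
    all_visits = [v for _, vs in cohort.patients for v in vs]
    if not all_visits:
        return GeneratorReport(0.0, 0.0, 0.0, 0.0, {}, 0.0)
    rule_freq = {}
    for d, m, _, _k in config.rule_table:
        dc, mc = _diag_code(d), med_code(m)
        with_d = [v for v in all_visits if dc in v.diagnoses]
        rule_freq[(d, m)] = (
            sum(1 for v in with_d if mc in v.medications) / len(with_d)
            if with_d else float("nan"))
    ddi_hits = total_pairs = 0
    for v in all_visits:
        meds = sorted(v.medications)
        total_pairs += len(meds) * (len(meds) - 1) // 2
        planted = {(med_code(min(a, b)), med_code(max(a, b)))
                   for a, b in config.ddi_pairs}
        for i in range(len(meds)):
            for j in range(i + 1, len(meds)):
                if (meds[i], meds[j]) in planted:
                    ddi_hits += 1
    return GeneratorReport(
        mean_visits=float(np.mean(n_visits_per_patient)),
        mean_diag=float(np.mean([len(v.diagnoses) for v in all_visits])),
        mean_proc=float(np.mean([len(v.procedures) for v in all_visits])),
        mean_med=float(np.mean([len(v.medications) for v in all_visits])),
        rule_conditional_freq=rule_freq,
        ddi_coprescription_rate=ddi_hits / total_pairs if total_pairs else 0.0,
    )


def validate_against_profile(report: GeneratorReport, profile: dict[str, float],
                             tol: float = 0.15) -> tuple[bool, list[str]]:
    """Check each realized mean against the target profile within tol."""
    problems = []
    for key, target in profile.items():
        realized = getattr(report, key)
        if abs(realized - target) > tol:
            problems.append(f"{key}: realized {realized:.4f} vs target "
                            f"{target:.4f} (tol {tol})")
    return (not problems, problems)


def ddi_pair_codes(config: SynthConfig) -> list[tuple[str, str]]:
    return [(med_code(a), med_code(b)) for a, b in config.ddi_pairs]


# Desk-scale profiles: visit/diagnosis/procedure means follow the ICU
# cohorts the recommender targets; vocabularies are kept small so every
# experiment runs on one CPU.  Rules map the first 12 diagnosis codes to the
# 18 medications; two 3-medication co-prescription clusters carry one
# planted contraindicated pair each.
def _standard_rules(firing: float = 0.9) -> list[tuple]:
    # 12 chronic single-occurrence rules plus 4 escalation rules that
    # require the diagnosis in two distinct visits before therapy starts
    plain = [(d, d % 18, firing) for d in range(12)]
    burden = [(12 + i, 12 + i, firing, 2) for i in range(4)]
    return plain + burden


PROFILES: dict[str, SynthConfig] = {
    "mimic3_like": SynthConfig(
        n_patients=1000, n_diag=200, n_proc=100, n_med=18,
        mean_visits=2.3460, mean_diag=10.8927, mean_proc=4.0463,
        rule_table=_standard_rules(), copair_clusters=[[0, 1, 2], [3, 4, 5]],
        copair_prob=0.5, ddi_pairs=[(0, 1), (3, 4)], noise_rate=0.01,
        persistence=0.5),
    "mimic4_like": SynthConfig(
        n_patients=2000, n_diag=200, n_proc=100, n_med=18,
        mean_visits=2.8169, mean_diag=9.3666, mean_proc=2.5492,
        rule_table=_standard_rules(), copair_clusters=[[0, 1, 2], [3, 4, 5]],
        copair_prob=0.5, ddi_pairs=[(0, 1), (3, 4)], noise_rate=0.01,
        persistence=0.5),
}


def profile_config(name: str, n_patients: int | None = None,
                   seed: int = 0, **overrides) -> SynthConfig:
    """A copy of a shipped profile with optional overrides."""
    import copy
    if name not in PROFILES:
        raise KeyError(f"unknown profile {name!r}; have {sorted(PROFILES)}")
    cfg = copy.deepcopy(PROFILES[name])
    if n_patients is not None:
        cfg.n_patients = n_patients
    cfg.seed = seed
    for k, v in overrides.items():
        if not hasattr(cfg, k):
            raise AttributeError(f"SynthConfig has no field {k!r}")
        setattr(cfg, k, v)
    cfg.__post_init__()
    return cfg
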