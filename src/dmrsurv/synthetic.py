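"""Synthetic cohorts with known ground truth for every pipeline stage.

Three generators emulate the data the pipeline consumes:

* a CpG-island probe map (BED-like annotation of 45-60 bp array probes
  grouped into islands),
* two-channel tumor/normal array cohorts with hypermethylated regions
  planted in a known carrier group,
* quantitative methylation panels (CpG-unit × patient fractions with
  missingness) tied to a proportional-hazards survival structure.

Every generator is a pure function of its seed and parameters, and every
planted signal is emitted alongside the data so tests can score recovery.
The defaults mirror a rectal-cancer prognosis study design: cohort sizes
11 / 61 / 71 / 42, disease-free survival with a 60-month follow-up horizon,
a bad-vs-good hazard ratio of 4, and a hypermethylated good-prognosis group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ArrayCohort",
    "SyntheticPanel",
    "default_panel",
    "generate_probe_map",
    "generate_array_cohort",
    "generate_methylation_cohort",
    "generate_survival",
    "write_probe_map",
    "load_probe_map",
]

PROBE_MAP_COLUMNS = ["chrom", "start", "end", "probe_id", "island_id"]

#: Probe length range of the emulated CpG-island array (bp).
PROBE_LENGTH = (45, 60)

#: Default survival structure: baseline (good-prognosis) hazard in events per
#: month chosen so 36-month disease-free survival is ~0.81, follow-up horizon
#: 60 months, and a bad-vs-good hazard ratio of 4.
DEFAULT_BASELINE_RATE = 0.006
DEFAULT_CENSOR_HORIZON = 60.0
DEFAULT_LOG_HR = float(np.log(4.0))


def _check_range(name, rng_pair, low=None, high=None):
    lo, hi = int(rng_pair[0]), int(rng_pair[1])
    if lo > hi:
        raise ValueError(f"{name} range is empty: {rng_pair}")
    if low is not None and lo < low:
        raise ValueError(f"{name} must be >= {low}")
    if high is not None and hi > high:
        raise ValueError(f"{name} max must be <= {high}")
    return lo, hi


def generate_probe_map(
    seed: int,
    n_chrom: int = 4,
    islands_per_chrom: int = 50,
    probes_per_island: tuple[int, int] = (3, 8),
    intra_spacing: tuple[int, int] = (50, 400),
    inter_island_gap: int = 10_000,
) -> pd.DataFrame:
    """Simulate a sorted, non-overlapping CpG-island probe annotation.

    Consecutive probes within an island are separated by an end-to-start gap
    drawn uniformly from ``intra_spacing`` (max 500 bp, so an island is a
    single coherent region for the DMR caller); islands are separated by at
    least ``inter_island_gap``.  Probe lengths are uniform on 45-60 bp.

    Returns a DataFrame with columns chrom, start, end, probe_id, island_id
    (0-based, half-open coordinates).
    """
    if n_chrom <= 0 or islands_per_chrom <= 0:
        raise ValueError("n_chrom and islands_per_chrom must be positive")
    p_lo, p_hi = _check_range("probes_per_island", probes_per_island, low=1)
    s_lo, s_hi = _check_range("intra_spacing", intra_spacing, low=0, high=500)
    if inter_island_gap < 10_000:
        raise ValueError("inter_island_gap must be >= 10000 bp")
    rng = np.random.default_rng(seed)
    rows = []
    probe_no = 0
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        pos = 1_000
        for ii in range(islands_per_chrom):
            island_id = f"{chrom}_isl{ii + 1:04d}"
            n_probes = int(rng.integers(p_lo, p_hi + 1))
            for pi in range(n_probes):
                length = int(rng.integers(PROBE_LENGTH[0], PROBE_LENGTH[1] + 1))
                start = pos
                end = start + length
                probe_no += 1
                rows.append((chrom, start, end, f"probe_{probe_no:06d}", island_id))
                pos = end + int(rng.integers(s_lo, s_hi + 1))
            pos += inter_island_gap + int(rng.integers(0, 5_000))
    return pd.DataFrame(rows, columns=PROBE_MAP_COLUMNS)


def write_probe_map(probe_map: pd.DataFrame, path) -> None:
    """Write the annotation as 5-column BED-like TSV (0-based, half-open)."""
    probe_map[PROBE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def load_probe_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "probe_id": str, "island_id": str})
    missing = [c for c in PROBE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"probe map missing columns: {missing}")
    return df


@dataclass
class ArrayCohort:
    """Two-channel array screening cohort with planted hypermethylation truth.

    ``intensities`` maps channel name (tumor_fg, tumor_bg, normal_fg,
    normal_bg) to a samples × probes DataFrame.  ``truth`` maps planted
    region (island) id to its probe ids and carrier sample ids; ``true_m``
    holds the noise-bearing ground-truth M-values the channels encode.
    """

    probe_map: pd.DataFrame
    samples: pd.DataFrame  # index sample_id; columns group, ypN, responder
    intensities: dict[str, pd.DataFrame]
    truth: dict[str, dict]
    true_m: pd.DataFrame = field(repr=False)
    effect: float = 0.0

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def category_samples(self, category: str) -> list[str]:
        """Sample ids of a clinical surrogate category.

        Categories follow post-therapy nodal status and therapy response:
        ``ypN+``/``ypN-`` and ``responder``/``non-responder``.
        """
        s = self.samples
        sel = {
            "ypN+": s["ypN"] == 1,
            "ypN-": s["ypN"] == 0,
            "responder": s["responder"] == 1,
            "non-responder": s["responder"] == 0,
        }
        if category not in sel:
            raise KeyError(f"unknown category {category!r}; expected one of {list(sel)}")
        return list(s.index[sel[category]])


def generate_array_cohort(
    probe_map: pd.DataFrame,
    n_samples: int = 11,
    n_planted: int = 30,
    effect: float = 2.0,
    noise_sd: float = 0.5,
    group_assignment: list[str] | None = None,
    seed: int = 0,
    a_level: float = 10.0,
    a_jitter_sd: float = 2.0,
    background: float = 30.0,
) -> ArrayCohort:
    """Simulate a tumor/mucosa co-hybridization cohort with planted DMRs.

    Baseline true M-values are Normal(0, ``noise_sd``); probes of a planted
    island get ``+effect`` in every carrier sample.  Carriers are the
    good-prognosis samples (the hypermethylated direction), which are also
    ypN-negative responders, so planted regions are recoverable through any
    clinical category.  Channel intensities are back-computed so that
    ``log2((tumor_fg-tumor_bg)/(normal_fg-normal_bg))`` equals the true M
    exactly, at average log2-intensity ``a_level`` plus per-probe jitter.
    """
    if effect <= 0:
        raise ValueError("effect must be positive (hypermethylation direction)")
    if n_samples < 2:
        raise ValueError("need at least two samples")
    island_sizes = probe_map.groupby("island_id", sort=False).size()
    multi = island_sizes.index[island_sizes >= 2]
    if n_planted > len(multi):
        raise ValueError(
            f"n_planted={n_planted} exceeds the {len(multi)} multi-probe islands"
        )
    rng = np.random.default_rng(seed)
    if group_assignment is None:
        n_good = n_samples - n_samples // 2
        group_assignment = ["good"] * n_good + ["bad"] * (n_samples - n_good)
    if len(group_assignment) != n_samples:
        raise ValueError("group_assignment length must equal n_samples")
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "group": group_assignment,
            "ypN": [0 if g == "good" else 1 for g in group_assignment],
            "responder": [1 if g == "good" else 0 for g in group_assignment],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    carriers = [sid for sid, g in zip(sample_ids, group_assignment) if g == "good"]

    probe_ids = list(probe_map["probe_id"])
    n_probes = len(probe_ids)
    planted = sorted(rng.choice(multi, size=n_planted, replace=False))
    probe_pos = {p: i for i, p in enumerate(probe_ids)}

    M = rng.normal(0.0, noise_sd, size=(n_samples, n_probes)) if noise_sd > 0 else np.zeros(
        (n_samples, n_probes)
    )
    truth: dict[str, dict] = {}
    carrier_rows = [sample_ids.index(s) for s in carriers]
    for isl in planted:
        members = probe_map.loc[probe_map["island_id"] == isl, "probe_id"].tolist()
        cols = [probe_pos[p] for p in members]
        M[np.ix_(carrier_rows, cols)] += effect
        sub = probe_map[probe_map["island_id"] == isl]
        truth[isl] = {
            "chrom": str(sub["chrom"].iloc[0]),
            "start": int(sub["start"].min()),
            "end": int(sub["end"].max()),
            "probe_ids": members,
            "carriers": carriers,
            "effect": effect,
        }

    jitter = rng.normal(0.0, a_jitter_sd, size=(n_samples, n_probes)) if a_jitter_sd > 0 else 0.0
    a_true = a_level + jitter
    normal_signal = np.exp2(a_true - M / 2.0)
    tumor_signal = np.exp2(a_true + M / 2.0)
    idx = pd.Index(sample_ids, name="sample_id")
    cols = pd.Index(probe_ids, name="probe_id")
    intensities = {
        "tumor_fg": pd.DataFrame(tumor_signal + background, index=idx, columns=cols),
        "tumor_bg": pd.DataFrame(np.full_like(M, background), index=idx, columns=cols),
        "normal_fg": pd.DataFrame(normal_signal + background, index=idx, columns=cols),
        "normal_bg": pd.DataFrame(np.full_like(M, background), index=idx, columns=cols),
    }
    return ArrayCohort(
        probe_map=probe_map,
        samples=samples,
        intensities=intensities,
        truth=truth,
        true_m=pd.DataFrame(M, index=idx, columns=cols),
        effect=effect,
    )


@dataclass
class SyntheticPanel:
    """Design of a quantitative methylation panel with planted prognosis signal.

    ``group_effect`` maps region id to the mean methylation shift of the
    good-prognosis group (0 for null regions); shifts must keep means inside
    (0, 1).  ``beta_dispersion`` is the Beta concentration (a+b).
    """

    cpg_ids: list[str]
    region_map: dict[str, str]
    baseline: float = 0.35
    group_effect: dict[str, float] = field(default_factory=dict)
    beta_dispersion: float = 30.0
    missing_rate: float = 0.10
    true_log_hr: float = DEFAULT_LOG_HR
    censor_horizon: float = DEFAULT_CENSOR_HORIZON
    baseline_rate: float = DEFAULT_BASELINE_RATE

    def __post_init__(self):
        if not 0 <= self.missing_rate < 0.6:
            raise ValueError("missing_rate must be in [0, 0.6) so samples survive the filter")
        if self.beta_dispersion <= 0:
            raise ValueError("beta_dispersion must be positive")
        for rid, shift in self.group_effect.items():
            m = self.baseline + shift
            if not (0 < m < 1) or not (0 < self.baseline < 1):
                raise ValueError(
                    f"region {rid}: shifted mean {m} outside (0, 1)"
                )

    def cpg_effect(self, cpg: str) -> float:
        return self.group_effect.get(self.region_map[cpg], 0.0)


def default_panel(
    n_prognostic_regions: int = 10,
    n_null_cpgs: int = 100,
    group_effect: float = 0.30,
    cpgs_per_null_region: int = 2,
    **kwargs,
) -> SyntheticPanel:
    """Panel with one CpG per prognostic region plus null filler CpGs.

    The default (10 prognostic CpGs among 100 null ones) mirrors a
    20-DMR candidate panel reduced to a 10-region signature.
    """
    cpg_ids, region_map, effects = [], {}, {}
    for i in range(n_prognostic_regions):
        rid = f"DMR{i + 1:02d}"
        cid = f"{rid}_CpG1"
        cpg_ids.append(cid)
        region_map[cid] = rid
        effects[rid] = group_effect
    for j in range(n_null_cpgs):
        rid = f"NULL{j // cpgs_per_null_region + 1:03d}"
        cid = f"cpg_null_{j + 1:03d}"
        cpg_ids.append(cid)
        region_map[cid] = rid
        effects.setdefault(rid, 0.0)
    return SyntheticPanel(cpg_ids=cpg_ids, region_map=region_map,
                          group_effect=effects, **kwargs)


def generate_survival(
    labels,
    true_log_hr: float = DEFAULT_LOG_HR,
    baseline_rate: float = DEFAULT_BASELINE_RATE,
    censor_horizon: float = DEFAULT_CENSOR_HORIZON,
    seed: int = 0,
    random_censor_rate: float = 0.0,
) -> pd.DataFrame:
    """Exponential proportional-hazards survival for labelled patients.

    Hazard is ``baseline_rate * exp(true_log_hr)`` for the bad-prognosis
    group and ``baseline_rate`` otherwise; event times past the follow-up
    horizon are censored at the horizon, with optional independent
    exponential censoring at ``random_censor_rate``.  Age, gender and
    ultrasound nodal status (uN) covariates are drawn independently of
    outcome.  ``labels`` may be a sequence or a pd.Series indexed by
    patient id.
    """
    if baseline_rate <= 0 or censor_horizon <= 0:
        raise ValueError("baseline_rate and censor_horizon must be positive")
    labels = pd.Series(labels)
    if len(labels) == 0:
        raise ValueError("empty label list")
    if not labels.index.dtype == object:
        labels.index = [f"P{i + 1:03d}" for i in range(len(labels))]
    rng = np.random.default_rng(seed)
    hazard = baseline_rate * np.exp(true_log_hr * (labels.to_numpy() == "bad"))
    event_time = rng.exponential(1.0 / hazard)
    time = event_time.copy()
    event = np.ones(len(labels), dtype=int)
    if random_censor_rate > 0:
        ct = rng.exponential(1.0 / random_censor_rate, size=len(labels))
        censored = ct < time
        time[censored] = ct[censored]
        event[censored] = 0
    if np.isfinite(censor_horizon):
        over = time > censor_horizon
        time[over] = censor_horizon
        event[over] = 0
    time = np.maximum(time, 1e-3)  # times must be strictly positive
    age = np.clip(np.round(rng.normal(64.0, 10.0, len(labels)), 1), 36.0, 85.0)
    gender = np.where(rng.random(len(labels)) < 0.7, "male", "female")
    uN = (rng.random(len(labels)) < 0.7).astype(int)
    return pd.DataFrame(
        {
            "time_months": np.round(time, 4),
            "event": event,
            "age": age,
            "gender": gender,
            "uN": uN,
        },
        index=pd.Index(labels.index, name="patient_id"),
    )


def generate_methylation_cohort(
    panel: SyntheticPanel,
    n_patients: int = 61,
    group_fractions: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Simulate a CpG × patient methylation matrix with linked survival.

    Good-prognosis patients are the *high*-methylation group: their
    prognostic-CpG Beta means sit ``group_effect`` above the bad group's
    baseline.  Returns (matrix, survival table, true group labels).
    """
    if n_patients < 4:
        raise ValueError("need at least 4 patients")
    f_good, f_bad = group_fractions
    if abs(f_good + f_bad - 1.0) > 1e-9:
        raise ValueError("group_fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_good = int(round(f_good * n_patients))
    labels = np.array(["good"] * n_good + ["bad"] * (n_patients - n_good))
    rng.shuffle(labels)
    patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    labels = pd.Series(labels, index=pd.Index(patient_ids, name="patient_id"), name="group")

    conc = panel.beta_dispersion
    good_mask = labels.to_numpy() == "good"
    values = np.empty((len(panel.cpg_ids), n_patients))
    for i, cpg in enumerate(panel.cpg_ids):
        mean = np.where(good_mask, panel.baseline + panel.cpg_effect(cpg), panel.baseline)
        values[i] = rng.beta(mean * conc, (1.0 - mean) * conc)
    if panel.missing_rate > 0:
        mask = rng.random(values.shape) < panel.missing_rate
        values[mask] = np.nan
    matrix = pd.DataFrame(
        values, index=pd.Index(panel.cpg_ids, name="cpg_id"), columns=patient_ids
    )
    surv_seed = int(rng.integers(0, 2**31 - 1))
    survival = generate_survival(
        labels,
        true_log_hr=panel.true_log_hr,
        baseline_rate=panel.baseline_rate,
        censor_horizon=panel.censor_horizon,
        seed=surv_seed,
    )
    return matrix, survival, labels
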