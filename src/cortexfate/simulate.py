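"""Synthetic nCounter-like panel data with full ground truth.

The generative model emulates the statistical structure the analysis
pipeline assumes about PSC-derived neural differentiations:

* five regional expression programs (cortex, LGE, MGE, mid/hindbrain,
  hypothalamus) over a compact marker panel;
* per-line latent signaling means (Wnt, Hedgehog); each differentiation
  draws its own latent activity around them, which maps through a
  softmax-Dirichlet link to mixture proportions over the programs —
  higher Wnt pushes mass toward cortex (and, at high levels,
  mid/hindbrain), higher Hedgehog toward MGE/LGE, low Wnt toward MGE;
* signaling readout genes (AXIN2/TNFRSF19 for Wnt; SHH/PTCH1/GLI1 up and
  GAS1 down for Hedgehog) scale monotonically with the latent activities;
* counts are negative-binomial around lane-scaled expected expression,
  with negative/positive control probes and housekeeping genes drawn
  around lane-scaled references.

Every generator is a pure function of (config, seed) and stores the full
ground truth (proportions, latent signaling, true outcome label, lane
factor) so any downstream inference can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CodesetDefinition, CountMatrix, RegionalProfileSet, SampleMetadata

REGIONS = ("cortex", "LGE", "MGE", "mid_hindbrain", "hypothalamus")

REGION_MARKERS: dict[str, tuple[str, ...]] = {
    "cortex": ("EMX1", "EMX2", "EOMES", "PAX6", "NEUROG2"),
    "LGE": ("DLX1", "DLX5"),
    "MGE": ("NKX2-1", "LHX6", "LHX8"),
    "mid_hindbrain": ("HOXA2", "HOXB2", "PAX3", "EN2", "GBX2", "TFAP2A"),
    "hypothalamus": ("OTP", "SIM1"),
}

SECONDARY_MARKERS: dict[str, tuple[str, ...]] = {
    "cortex": ("TBR1", "SLC17A7", "FEZF2"),
    "LGE": ("GSX2", "SP8"),
    "MGE": ("OLIG2", "SST"),
    "mid_hindbrain": ("OTX2", "NR4A2"),
    "hypothalamus": ("NKX2-2", "RAX"),
}

FOREBRAIN_PROGRAMS = ("cortex", "LGE", "MGE", "hypothalamus")
PAN_NEURAL = ("MAP2", "TUBB3", "NES", "SOX2", "VIM", "NCAM1")
LOW_EXPRESSED = ("ALB", "CDX2", "MYOD1", "TNNT2", "AFP", "SOX17")

#: panel genes expressed independently of regional identity (neural
#: adhesion/guidance/Notch programs); they dilute the axis signal the way
#: the real codesets' non-regional probes do
NEUTRAL_GENES = (
    "STMN2", "DCX", "MAPT", "GFAP", "S100B", "SOX1", "CDH2", "NCAM2",
    "ROBO1", "ROBO2", "SLIT1", "NTRK2", "BDNF", "CNTN2", "L1CAM", "NRCAM",
    "EFNB2", "EPHA4", "NOTCH1", "HES1", "HES5", "DLL1", "JAG1", "ID2",
)

WNT_READOUTS = {"AXIN2": 0.9, "TNFRSF19": 0.8}
HH_READOUTS = {"SHH": 1.0, "PTCH1": 0.8, "GLI1": 0.8, "GAS1": -0.8}

HOUSEKEEPING_MEANS = {
    "CLTC": 900.0, "GAPDH": 3200.0, "GUSB": 600.0, "PPIA": 2600.0,
    "RPLP1": 2900.0, "RPS15A": 2300.0, "RPS9": 2000.0,
}
NEGATIVE_PROBES = tuple(f"NEG_{c}" for c in "ABCDEFGH")      # 8
POSITIVE_PROBES = tuple(f"POS_{c}" for c in "ABCDEF")        # 6
POSITIVE_CONC = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)          # fM ladder A-F

OUTCOME_LABELS = (
    "dorsalized", "partially_ventralized", "highly_ventralized",
    "partially_caudalized", "highly_caudalized",
)

#: study-design roster: line, differentiations, latent means, genotype.
#: 27 lines / 149 differentiations; most lines dorsal-prone, a few
#: partially or highly ventral-prone, one partially and one highly
#: caudal-prone line (the latter mirroring a line with consistent
#: caudalized outcomes).
LINE_TABLE: tuple[tuple[str, int, float, float, str], ...] = (
    ("L01.1", 26, 1.30, -0.90, "control"),
    ("L02.1", 12, 1.10, -0.70, "control"),
    ("L03.1", 10, 1.40, -1.00, "control"),
    ("L04.1", 8, 1.20, -0.60, "MAPT"),
    ("L05.1", 7, 1.00, -0.90, "control"),
    ("L06.1", 6, 1.30, -0.50, "TS21"),
    ("L07.1", 6, 1.20, -1.10, "control"),
    ("L08.1", 5, 1.50, -0.80, "AD"),
    ("L09.1", 5, 0.90, -0.70, "control"),
    ("L10.1", 4, 1.10, -1.00, "TS21"),
    ("L11.1", 4, 1.35, -0.75, "control"),
    ("L12.1", 3, 1.25, -0.85, "MAPT"),
    ("L13.1", 3, 1.00, -0.50, "control"),
    ("L14.1", 3, 1.15, -0.95, "AD"),
    ("L15.1", 2, 1.30, -0.70, "control"),
    ("L16.1", 2, 1.05, -0.80, "TS21"),
    ("L17.1", 2, 1.20, -0.90, "control"),
    ("L18.1", 2, 1.40, -0.60, "control"),
    ("L19.1", 5, 0.45, 0.65, "control"),
    ("L20.1", 4, 0.35, 0.70, "control"),
    ("L21.1", 3, 0.50, 0.60, "MAPT"),
    ("L22.1", 8, -0.40, 1.30, "control"),
    ("L23.1", 6, -0.30, 1.25, "control"),
    ("L24.1", 5, -0.50, 1.40, "control"),
    ("L25.1", 3, -0.35, 1.20, "control"),
    ("L26.1", 2, 3.20, -0.50, "control"),
    ("L27.1", 3, 4.20, -0.50, "MAPT"),
)

VENTRAL_PRONE_LINES = ("L22.1", "L23.1", "L24.1", "L25.1")
DORSAL_PRONE_LINE = "L01.1"


@dataclass
class SimConfig:
    """Generator constants (linear-scale means unless noted)."""

    marker_home_mean: float = 480.0
    marker_off_mean: float = 30.0
    secondary_home_mean: float = 240.0
    secondary_off_mean: float = 30.0
    foxg1_forebrain_mean: float = 600.0
    foxg1_caudal_mean: float = 25.0
    pan_neural_mean: float = 300.0
    low_expressed_mean: float = 8.0
    readout_base_mean: float = 120.0
    background_mean: float = 3.0      # nonspecific signal on endogenous probes
    negative_mean: float = 4.0
    positive_scale: float = 150.0     # counts per fM of the positive ladder
    dirichlet_kappa: float = 150.0    # mixture concentration (tight outcomes)
    latent_sd: float = 0.25           # per-differentiation latent spread
    lane_sd: float = 0.15             # log-normal lane scale factor sd
    nb_size: float = 60.0             # negative-binomial size (overdispersion)
    control_nb_size: float = 200.0    # control probes are technically tighter
    readout_log2_coef: float = 1.0    # multiplies per-gene readout coefficients

    def __post_init__(self) -> None:
        if self.dirichlet_kappa <= 0 or self.nb_size <= 0:
            raise ValueError("dispersion parameters must be positive")


def panel_genes() -> list[str]:
    genes: list[str] = ["FOXG1"]
    for r in REGIONS:
        genes += list(REGION_MARKERS[r]) + list(SECONDARY_MARKERS[r])
    genes += list(PAN_NEURAL) + list(NEUTRAL_GENES) + list(LOW_EXPRESSED)
    genes += list(WNT_READOUTS) + list(HH_READOUTS)
    return genes


def program_means(cfg: SimConfig | None = None) -> pd.DataFrame:
    """Regional program means, programs x genes (linear scale).

    Each region marker is elevated at least 8-fold in its home program;
    FOXG1 is high in all forebrain programs; pan-neural genes are shared.
    """
    cfg = cfg or SimConfig()
    genes = panel_genes()
    M = pd.DataFrame(0.0, index=list(REGIONS), columns=genes)
    for r in REGIONS:
        for g in REGION_MARKERS[r]:
            M.loc[:, g] = cfg.marker_off_mean
            M.loc[r, g] = cfg.marker_home_mean
        for g in SECONDARY_MARKERS[r]:
            M.loc[:, g] = cfg.secondary_off_mean
            M.loc[r, g] = cfg.secondary_home_mean
    # re-apply home values (loops above reset whole columns)
    for r in REGIONS:
        for g in REGION_MARKERS[r]:
            M.loc[r, g] = cfg.marker_home_mean
        for g in SECONDARY_MARKERS[r]:
            M.loc[r, g] = cfg.secondary_home_mean
    M["FOXG1"] = cfg.foxg1_caudal_mean
    M.loc[list(FOREBRAIN_PROGRAMS), "FOXG1"] = cfg.foxg1_forebrain_mean
    for g in PAN_NEURAL:
        M[g] = cfg.pan_neural_mean
    for i, g in enumerate(NEUTRAL_GENES):
        # fixed per-gene levels spanning the panel's dynamic range
        M[g] = 60.0 * 2.0 ** (2.5 * i / max(len(NEUTRAL_GENES) - 1, 1))
    for g in LOW_EXPRESSED:
        M[g] = cfg.low_expressed_mean
    for g in list(WNT_READOUTS) + list(HH_READOUTS):
        M[g] = cfg.readout_base_mean
    _validate_programs(M)
    return M


def _validate_programs(M: pd.DataFrame, min_fold: float = 8.0) -> None:
    if (M.to_numpy() < 0).any():
        raise ValueError("program means must be non-negative")
    for r in REGIONS:
        for g in REGION_MARKERS[r]:
            home = M.loc[r, g]
            off = M.loc[[s for s in REGIONS if s != r], g].max()
            if home < min_fold * off:
                raise ValueError(
                    f"marker {g} only {home / off:.1f}-fold enriched in {r}"
                )


def signaling_to_proportions(
    wnt: float, hh: float, rng: np.random.Generator, cfg: SimConfig,
) -> np.ndarray:
    """Map latent (Wnt, Hh) activity to Dirichlet mixture proportions."""
    scores = np.array([
        1.2 + wnt - hh,            # cortex
        0.3 + 0.6 * (hh - wnt),    # LGE
        1.5 * hh - wnt - 0.3,      # MGE (high Hh or low Wnt)
        3.0 * (wnt - 1.8),         # mid/hindbrain (only very high Wnt)
        -1.8,                      # hypothalamus (rare, constant low)
    ])
    p = np.exp(scores - scores.max())
    p /= p.sum()
    alpha = cfg.dirichlet_kappa * p
    draw = rng.dirichlet(alpha)
    if not np.isclose(draw.sum(), 1.0):
        raise ValueError("mixture proportions are not simplex-valued")
    return draw


#: fixed proportion thresholds defining the ground-truth outcome label
TRUE_LABEL_RULE = {
    "mid_hindbrain_high": 0.45,
    "mid_hindbrain_low": 0.25,
    "mge_high": 0.40,
    "mge_low": 0.15,
}


def true_label(proportions: np.ndarray) -> str:
    """Outcome label from mixture proportions (fixed threshold rule)."""
    p = dict(zip(REGIONS, proportions))
    r = TRUE_LABEL_RULE
    if p["mid_hindbrain"] > r["mid_hindbrain_high"]:
        return "highly_caudalized"
    if p["mid_hindbrain"] > r["mid_hindbrain_low"]:
        return "partially_caudalized"
    if p["MGE"] > r["mge_high"]:
        return "highly_ventralized"
    if p["MGE"] > r["mge_low"]:
        return "partially_ventralized"
    return "dorsalized"


def expected_expression(
    proportions: np.ndarray, wnt: float, hh: float, cfg: SimConfig,
    programs: pd.DataFrame,
) -> pd.Series:
    """Proportion-weighted program means with signaling-readout scaling."""
    e = pd.Series(proportions @ programs.to_numpy(), index=programs.columns)
    for g, coef in WNT_READOUTS.items():
        e[g] = cfg.readout_base_mean * 2.0 ** (cfg.readout_log2_coef * coef * wnt)
    for g, coef in HH_READOUTS.items():
        e[g] = cfg.readout_base_mean * 2.0 ** (cfg.readout_log2_coef * coef * hh)
    return e


def simulation_codeset(codeset_id: str = "SimCodeset") -> CodesetDefinition:
    rows = [(g, g, "endogenous", "") for g in panel_genes()]
    rows += [(g, g, "housekeeping", "") for g in HOUSEKEEPING_MEANS]
    rows += [(p, p, "negative", "") for p in NEGATIVE_PROBES]
    rows += [(p, p, "positive", rank)
             for p, rank in zip(POSITIVE_PROBES, "ABCDEF")]
    probes = pd.DataFrame(rows, columns=["probe_id", "gene_symbol",
                                         "probe_class", "pos_rank"])
    return CodesetDefinition(codeset_id=codeset_id, probes=probes)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _draw_counts(
    rng: np.random.Generator, expected: pd.Series, lane: float, cfg: SimConfig,
) -> pd.Series:
    """One sample's raw probe counts (endogenous + controls), lane-scaled."""
    endo = _nb_draw(rng, lane * (expected.to_numpy() + cfg.background_mean),
                    cfg.nb_size)
    hk = _nb_draw(rng, lane * np.array(list(HOUSEKEEPING_MEANS.values())),
                  cfg.control_nb_size)
    neg = _nb_draw(rng, lane * np.full(len(NEGATIVE_PROBES), cfg.negative_mean),
                   cfg.control_nb_size)
    pos = _nb_draw(rng, lane * cfg.positive_scale * np.array(POSITIVE_CONC),
                   cfg.control_nb_size)
    return pd.Series(
        np.concatenate([endo, hk, neg, pos]),
        index=(list(expected.index) + list(HOUSEKEEPING_MEANS)
               + list(NEGATIVE_PROBES) + list(POSITIVE_PROBES)),
    )


@dataclass
class GroundTruth:
    """Per-sample generator state, sufficient to score downstream inference."""

    table: pd.DataFrame  # indexed by sample_id

    def labels(self) -> pd.Series:
        return self.table["true_label"]

    def proportions(self) -> pd.DataFrame:
        return self.table[[f"p_{r}" for r in REGIONS]]


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    metadata: SampleMetadata
    truth: GroundTruth


def _line_roster(
    n_lines: int | None, diffs_per_line: int | Sequence[int] | None,
) -> list[tuple[str, int, float, float, str]]:
    roster = list(LINE_TABLE)
    if n_lines is not None:
        roster = roster[:n_lines]
    if diffs_per_line is not None:
        if isinstance(diffs_per_line, int):
            roster = [(l, diffs_per_line, w, h, g) for l, _, w, h, g in roster]
        else:
            if len(diffs_per_line) != len(roster):
                raise ValueError("diffs_per_line length != number of lines")
            roster = [(l, int(n), w, h, g)
                      for (l, _, w, h, g), n in zip(roster, diffs_per_line)]
    return roster


def simulate_dataset(
    n_lines: int | None = None,
    diffs_per_line: int | Sequence[int] | None = None,
    cfg: SimConfig | None = None,
    seed: int = 0,
    stage: str = "early",
    dpi: float = 17.0,
) -> SimulatedDataset:
    """Simulate one panel dataset: one sample per differentiation.

    Defaults reproduce the study design: the 27-line roster with 149
    differentiations in total.
    """
    cfg = cfg or SimConfig()
    programs = program_means(cfg)
    roster = _line_roster(n_lines, diffs_per_line)

    rows, meta_rows, truth_rows, ids = [], [], [], []
    uin = 0
    for li, (line, n_diffs, wnt_mu, hh_mu, genotype) in enumerate(roster):
        for d in range(n_diffs):
            uin += 1
            rng = np.random.default_rng([seed, li, d])
            wnt = wnt_mu + cfg.latent_sd * rng.standard_normal()
            hh = hh_mu + cfg.latent_sd * rng.standard_normal()
            props = signaling_to_proportions(wnt, hh, rng, cfg)
            lane = float(np.exp(cfg.lane_sd * rng.standard_normal()))
            e = expected_expression(props, wnt, hh, cfg, programs)
            counts = _draw_counts(rng, e, lane, cfg)
            sid = f"UIN{uin:04d}"
            ids.append(sid)
            rows.append(counts)
            meta_rows.append({
                "sample_id": sid, "uin": f"UIN{uin:04d}", "line": line,
                "individual": line.split(".")[0], "genotype": genotype,
                "stage": stage, "dpi": dpi, "treatment": "none",
                "operator": "",
            })
            truth_rows.append({
                "sample_id": sid, "line": line, "wnt": wnt, "hh": hh,
                **{f"p_{r}": p for r, p in zip(REGIONS, props)},
                "true_label": true_label(props), "lane_factor": lane,
                "treatment": "none",
            })

    counts_df = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    codeset = simulation_codeset()
    cm = CountMatrix(counts=counts_df.astype(np.int64),
                     probe_class=codeset.probe_class,
                     codeset_id=codeset.codeset_id)
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = GroundTruth(pd.DataFrame(truth_rows).set_index("sample_id"))
    return SimulatedDataset(cm, meta, truth)


def line_outcome_probabilities(
    line: str, n_mc: int = 4000, cfg: SimConfig | None = None, seed: int = 123,
) -> pd.Series:
    """Monte-Carlo outcome-label probabilities implied by a line's model.

    Draws latent signaling and mixture proportions (no counts) and applies
    the fixed true-label rule; used to score frequency estimates against
    the generator.
    """
    cfg = cfg or SimConfig()
    latent = {l: (w, h) for l, n, w, h, g in LINE_TABLE}
    if line not in latent:
        raise KeyError(f"unknown line {line!r}")
    wnt_mu, hh_mu = latent[line]
    rng = np.random.default_rng([seed, 9090])
    counts = {lab: 0 for lab in OUTCOME_LABELS}
    for _ in range(n_mc):
        wnt = wnt_mu + cfg.latent_sd * rng.standard_normal()
        hh = hh_mu + cfg.latent_sd * rng.standard_normal()
        props = signaling_to_proportions(wnt, hh, rng, cfg)
        counts[true_label(props)] += 1
    return pd.Series(counts, dtype=float) / n_mc


# ---------------------------------------------------------------------------
# time courses and treatments
# ---------------------------------------------------------------------------

#: latent activity shared by every differentiation before divergence
NEUTRAL_LATENT = (0.8, -0.2)

DEFAULT_TIMEPOINTS = (0.0, 4.0, 7.0, 12.0, 17.0, 35.0)


def _latent_at(
    t: float, divergence_dpi: float, wnt_mu: float, hh_mu: float,
) -> tuple[float, float]:
    if t < divergence_dpi:
        return NEUTRAL_LATENT
    return wnt_mu, hh_mu


def simulate_timecourse(
    lines: Mapping[str, str] | None = None,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    divergence_dpi: float = 17.0,
    cfg: SimConfig | None = None,
    seed: int = 0,
    diffs_per_line: int = 2,
) -> SimulatedDataset:
    """Simulate a differentiation time course with group divergence.

    ``lines`` maps line -> group; groups share one neutral latent
    trajectory before ``divergence_dpi`` and follow their line-specific
    latent means from that day on (``divergence_dpi = inf`` gives a null
    dataset with indistinguishable groups). One sample per differentiation
    per timepoint.
    """
    cfg = cfg or SimConfig()
    programs = program_means(cfg)
    if lines is None:
        lines = {DORSAL_PRONE_LINE: "dorsal_prone"}
        lines.update({l: "ventral_prone" for l in VENTRAL_PRONE_LINES})
    if not np.isinf(divergence_dpi) and not (
        min(timepoints) <= divergence_dpi <= max(timepoints)
    ):
        raise ValueError("divergence_dpi outside the timepoint range")
    latent_by_line = {l: (w, h) for l, _, w, h, _ in LINE_TABLE}

    rows, meta_rows, truth_rows, ids = [], [], [], []
    uin = 0
    for li, (line, group) in enumerate(sorted(lines.items())):
        wnt_mu, hh_mu = latent_by_line[line]
        for d in range(diffs_per_line):
            uin += 1
            rng = np.random.default_rng([seed, 7001, li, d])
            dw = cfg.latent_sd * rng.standard_normal()
            dh = cfg.latent_sd * rng.standard_normal()
            lane = float(np.exp(cfg.lane_sd * rng.standard_normal()))
            for t in timepoints:
                wnt0, hh0 = _latent_at(t, divergence_dpi, wnt_mu, hh_mu)
                wnt, hh = wnt0 + dw, hh0 + dh
                props = signaling_to_proportions(wnt, hh, rng, cfg)
                e = expected_expression(props, wnt, hh, cfg, programs)
                counts = _draw_counts(rng, e, lane, cfg)
                sid = f"TC{uin:03d}-d{int(t):02d}"
                ids.append(sid)
                rows.append(counts)
                meta_rows.append({
                    "sample_id": sid, "uin": f"TC{uin:03d}", "line": line,
                    "individual": line.split(".")[0], "genotype": "control",
                    "stage": "timecourse", "dpi": float(t),
                    "treatment": "none", "operator": "",
                })
                truth_rows.append({
                    "sample_id": sid, "line": line, "group": group,
                    "wnt": wnt, "hh": hh,
                    **{f"p_{r}": p for r, p in zip(REGIONS, props)},
                    "true_label": true_label(props), "lane_factor": lane,
                    "treatment": "none",
                })

    counts_df = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
    codeset = simulation_codeset()
    cm = CountMatrix(counts=counts_df.astype(np.int64),
                     probe_class=codeset.probe_class,
                     codeset_id=codeset.codeset_id)
    return SimulatedDataset(
        cm, SampleMetadata(pd.DataFrame(meta_rows)),
        GroundTruth(pd.DataFrame(truth_rows).set_index("sample_id")),
    )


TREATMENT_EFFECTS = {
    "wnt_up": (1.0, 0.0), "wnt_down": (-1.0, 0.0),
    "hh_up": (0.0, 1.0), "hh_down": (0.0, -1.0),
}


def simulate_treatment(
    effect: str = "wnt_up",
    magnitude: float = 1.5,
    lines: Sequence[str] = VENTRAL_PRONE_LINES,
    n_diffs: int = 7,
    cfg: SimConfig | None = None,
    seed: int = 0,
    dpi: float = 34.0,
) -> tuple[SimulatedDataset, SimulatedDataset]:
    """Paired treated/control differentiations profiled after treatment.

    The treated arm's latent signaling is shifted by ``magnitude`` along the
    targeted pathway before the mixture draw. Control and treated arms
    share per-differentiation seed streams, so a zero-magnitude effect
    yields byte-identical datasets and the paired contrast isolates the
    effect. Differentiations are spread round-robin over ``lines``.
    """
    if effect not in TREATMENT_EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    if magnitude < 0:
        raise ValueError("effect magnitude must be >= 0")
    cfg = cfg or SimConfig()
    programs = program_means(cfg)
    dw_eff, dh_eff = TREATMENT_EFFECTS[effect]
    latent_by_line = {l: (w, h) for l, _, w, h, _ in LINE_TABLE}

    arms: dict[str, tuple[list, list, list, list]] = {
        "control": ([], [], [], []), "treated": ([], [], [], []),
    }
    for d in range(n_diffs):
        line = lines[d % len(lines)]
        wnt_mu, hh_mu = latent_by_line[line]
        base_rng = np.random.default_rng([seed, 8002, d])
        dw = cfg.latent_sd * base_rng.standard_normal()
        dh = cfg.latent_sd * base_rng.standard_normal()
        for arm, shift in (("control", 0.0), ("treated", magnitude)):
            rng = np.random.default_rng([seed, 8002, d, 1])
            wnt = wnt_mu + dw + shift * dw_eff
            hh = hh_mu + dh + shift * dh_eff
            props = signaling_to_proportions(wnt, hh, rng, cfg)
            lane = float(np.exp(cfg.lane_sd * rng.standard_normal()))
            e = expected_expression(props, wnt, hh, cfg, programs)
            counts = _draw_counts(rng, e, lane, cfg)
            sid = f"TR{d + 1:03d}"  # same id in both arms: a paired design
            treatment = "none" if arm == "control" else effect
            rows, meta_rows, truth_rows, ids = arms[arm]
            ids.append(sid)
            rows.append(counts)
            meta_rows.append({
                "sample_id": sid, "uin": f"TR{d + 1:03d}", "line": line,
                "individual": line.split(".")[0], "genotype": "control",
                "stage": "late", "dpi": dpi, "treatment": treatment,
                "operator": "",
            })
            truth_rows.append({
                "sample_id": sid, "line": line, "wnt": wnt, "hh": hh,
                **{f"p_{r}": p for r, p in zip(REGIONS, props)},
                "true_label": true_label(props), "lane_factor": lane,
                "treatment": treatment,
            })

    codeset = simulation_codeset()
    out = []
    for arm in ("control", "treated"):
        rows, meta_rows, truth_rows, ids = arms[arm]
        counts_df = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"))
        out.append(SimulatedDataset(
            CountMatrix(counts=counts_df.astype(np.int64),
                        probe_class=codeset.probe_class,
                        codeset_id=codeset.codeset_id),
            SampleMetadata(pd.DataFrame(meta_rows)),
            GroundTruth(pd.DataFrame(truth_rows).set_index("sample_id")),
        ))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# atlas fixture
# ---------------------------------------------------------------------------

#: E11.5-style region-selective gene partition (27 genes, 5 regions)
ATLAS_SELECTIVE_GENES: dict[str, tuple[str, ...]] = {
    "RSP": ("GPC3", "FOXP2", "PTCH1", "SATB2", "RAX"),
    "subpallium": ("LHX6", "OLIG2", "DLX1", "LHX8", "GSC"),
    "pallium": ("MAP2", "FOXG1", "TBR1", "SLC17A7", "GLI3", "EOMES",
                "GAS1", "EMX1", "NEUROG2", "EMX2"),
    "midbrain": ("DDC", "NR4A2", "OTX2", "EN2"),
    "hindbrain": ("HOXB2", "NKX6-1", "HOXA2"),
}


def make_atlas_fixture(
    seed: int = 0,
    n_background: int = 140,
    boost: float = 60.0,
    noise_sd: float = 0.3,
    age_label: str = "E11.5",
) -> RegionalProfileSet:
    """Synthetic atlas expression-energy fixture.

    Energies are built so each gene of the printed-style selective partition
    is elevated ``boost``-fold in its home region over a shared correlated
    baseline, plus correlated background genes — suitable for exact recovery
    by :func:`cortexfate.atlas.select_region_specific_genes`.
    """
    rng = np.random.default_rng([seed, 4242])
    regions = list(ATLAS_SELECTIVE_GENES)
    genes = [g for gs in ATLAS_SELECTIVE_GENES.values() for g in gs]
    genes += [f"BG{i:03d}" for i in range(n_background)]
    base = 2.0 ** rng.normal(3.0, 1.0, size=len(genes))
    energy = np.empty((len(regions), len(genes)))
    for i, r in enumerate(regions):
        sel = set(ATLAS_SELECTIVE_GENES[r])
        for j, g in enumerate(genes):
            e = base[j] * (boost if g in sel else 1.0)
            energy[i, j] = e * 2.0 ** rng.normal(0.0, noise_sd)
    return RegionalProfileSet(
        energy=pd.DataFrame(energy, index=regions, columns=genes),
        age_label=age_label,
    )
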