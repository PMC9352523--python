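"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a hospitalized-pneumonia cohort
with a one-month follow-up and a control group:

* two genus-level metacommunities — an "undisrupted" one dominated by
  Bacteroides-, Lachnospiraceae- and Ruminococcaceae-like genera
  (including butyrate producers, higher alpha diversity) and a
  "disrupted" one dominated by facultative anaerobic peptococci-like
  genera (Finegoldia/Peptoniphilus/Anaerococcus-like, lower diversity);
* per-sample counts drawn from the Dirichlet-multinomial model the
  downstream clustering assumes (p ~ Dirichlet(alpha), counts ~
  Multinomial(depth, p), depths lognormal);
* analyte panels whose coupling to the community ordination axes is
  zero at admission and positive at the one-month timepoint, with
  per-analyte Gaussian noise;
* a follow-up subset of the admission patients, and clinical metadata
  (age, sex, comorbidity flags, prior antibiotics).

Every generated object carries its generating component and the true
analyte coupling, so parameter-recovery tests have ground truth.  One
global seed is split into per-stage substreams, making each stage
individually reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from skbio import TreeNode

from .diversity import pcoa, unifrac
from .io_formats import (CountTable, PhyloTree, ResponsePanel, SampleMetadata,
                         ValidationError)

logger = logging.getLogger(__name__)

# Curated genus names for the default 50-genus community: 12
# commensals, 10 butyrate producers, 5 peptococci-like disruptors,
# then generic fillers.
_COMMENSAL_GENERA = [
    "Bacteroides", "Prevotella", "Alistipes", "Parabacteroides", "Blautia",
    "Dorea", "Lachnospira", "Ruminococcus", "Fusicatenibacter", "Collinsella",
    "Bifidobacterium", "Akkermansia",
]
_BUTYRATE_GENERA = [
    "Faecalibacterium", "Roseburia", "Anaerostipes", "Coprococcus",
    "Butyrivibrio", "Subdoligranulum", "Eubacterium", "Butyricicoccus",
    "Flavonifractor", "Oscillibacter",
]
_DISRUPTOR_GENERA = [
    "Finegoldia", "Peptoniphilus", "Anaerococcus", "Peptococcus",
    "Murdochiella",
]

DEFAULT_ANALYTES = pd.DataFrame(
    [(f"{c}_{s}", s, cell)
     for c, cell in [("TNFa", "monocyte"), ("IFNg", "monocyte"),
                     ("IL1b", "monocyte"), ("IL6", "monocyte"),
                     ("IL10", "monocyte"), ("IL27", "monocyte"),
                     ("IL8", "PMN"), ("MPO", "PMN"),
                     ("Proteinase3", "PMN"), ("NGAL", "PMN")]
     for s in ("LPS", "Kpneumoniae")],
    columns=["analyte", "stimulus", "cell_type"],
).set_index("analyte")


def default_genus_names(n_genera: int) -> list[str]:
    base = _COMMENSAL_GENERA + _BUTYRATE_GENERA + _DISRUPTOR_GENERA
    if n_genera <= len(base):
        # keep the disruptors in any truncation so both metacommunities exist
        if n_genera < len(_DISRUPTOR_GENERA) + 5:
            raise ValidationError("n_genera too small for the default community")
        kept = base[: n_genera - len(_DISRUPTOR_GENERA)] + _DISRUPTOR_GENERA
        return kept
    return base + [f"Genus{i:03d}" for i in range(1, n_genera - len(base) + 1)]


def default_butyrate_reference() -> list[str]:
    """The packaged, editable reference list of butyrate-producing genera."""
    text = (resources.files("pneumobiome") / "data" / "butyrate_genera.txt").read_text()
    return [line.strip() for line in text.splitlines()
            if line.strip() and not line.startswith("#")]


def _default_alphas(genus_names: list[str]):
    """Metacommunity Dirichlet parameters.

    Component A ("undisrupted"): weight spread over commensals and
    butyrate producers, near-zero on the disruptors -> high diversity
    and high butyrate mass.  Component B ("disrupted"): concentrated on
    the peptococci-like disruptors -> low diversity, low butyrate mass.
    The separation (odds ratio ~100x on the dominant genera) keeps the
    mixture identifiable at the default depth.
    """
    butyrate = set(_BUTYRATE_GENERA)
    disruptors = set(_DISRUPTOR_GENERA)
    alpha_a = np.empty(len(genus_names))
    alpha_b = np.empty(len(genus_names))
    for i, g in enumerate(genus_names):
        if g in disruptors:
            alpha_a[i] = 0.05
            alpha_b[i] = 8.0
        elif g in butyrate:
            alpha_a[i] = 3.0
            alpha_b[i] = 0.08
        elif g in _COMMENSAL_GENERA:
            alpha_a[i] = 2.0
            alpha_b[i] = 0.3
        else:
            alpha_a[i] = 0.5
            alpha_b[i] = 0.3
    return alpha_a, alpha_b


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults give 150 samples (60 admission, 40 follow-up, 50 controls)
    over 50 genera at a median read depth of ~10,000 — large enough for
    stable UniFrac/DMM behavior, small enough for minutes-scale runs.
    ``coupling`` is analytes x 4 on standardized ordination axes, used
    at the month timepoint only; admission coupling is zero.
    """

    n_admission: int = 60
    n_month: int = 40
    n_controls: int = 50
    n_genera: int = 50
    genus_names: list[str] | None = None
    alpha_a: np.ndarray | None = None
    alpha_b: np.ndarray | None = None
    disrupted_fraction: float = 0.5
    depth_log_mean: float = float(np.log(10_000))
    depth_log_sd: float = 0.35
    butyrate_genus_ids: list[str] | None = None
    analytes: pd.DataFrame | None = None
    coupling: np.ndarray | None = None
    noise_sd: np.ndarray | float = 1.0
    n_axes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_admission", "n_month", "n_controls", "n_genera"):
            if getattr(self, name) < 0:
                raise ValidationError(f"config field {name} must be non-negative")
        if self.n_month > self.n_admission:
            raise ValidationError("config field n_month cannot exceed n_admission")
        if not 0.0 <= self.disrupted_fraction <= 1.0:
            raise ValidationError("config field disrupted_fraction must be in [0, 1]")
        if self.genus_names is None:
            self.genus_names = default_genus_names(self.n_genera)
        if len(self.genus_names) != self.n_genera:
            raise ValidationError("config field genus_names length != n_genera")
        if self.alpha_a is None or self.alpha_b is None:
            a, b = _default_alphas(self.genus_names)
            self.alpha_a = a if self.alpha_a is None else np.asarray(self.alpha_a)
            self.alpha_b = b if self.alpha_b is None else np.asarray(self.alpha_b)
        self.alpha_a = np.asarray(self.alpha_a, dtype=float)
        self.alpha_b = np.asarray(self.alpha_b, dtype=float)
        for name in ("alpha_a", "alpha_b"):
            vec = getattr(self, name)
            if vec.shape != (self.n_genera,) or (vec <= 0).any():
                raise ValidationError(f"config field {name} must be positive, "
                                      f"length n_genera")
        if self.butyrate_genus_ids is None:
            self.butyrate_genus_ids = [g for g in self.genus_names
                                       if g in set(_BUTYRATE_GENERA)]
        if self.analytes is None:
            self.analytes = DEFAULT_ANALYTES.copy()
        n_analytes = len(self.analytes)
        if self.coupling is None:
            # per-analyte coupling magnitudes span true explained
            # fractions from 0 up to ~15%, bracketing the weak,
            # heterogeneous microbiota-cytokine coupling regime
            fractions = np.linspace(0.0, 0.15, n_analytes)
            mags = np.sqrt(fractions / (1.0 - fractions))
            self.coupling = np.zeros((n_analytes, self.n_axes))
            for i, m in enumerate(mags):
                self.coupling[i, i % self.n_axes] = m
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (n_analytes, self.n_axes):
            raise ValidationError("config field coupling must be analytes x n_axes")
        if not np.isfinite(self.coupling).all():
            raise ValidationError("config field coupling must be finite")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (n_analytes,)).copy()
        if (self.noise_sd < 0).any():
            raise ValidationError("config field noise_sd must be non-negative")


@dataclass
class GroundTruth:
    """Generating labels and true coupling of a synthetic cohort."""

    components: pd.Series  # sample id -> "A" | "B"
    coupling: dict[str, np.ndarray]  # timepoint -> analytes x axes (std axes)
    true_explained: dict[str, pd.Series]  # timepoint -> per-analyte fraction


@dataclass
class Cohort:
    """All artifacts of one synthetic cohort draw."""

    counts: dict[str, CountTable]  # "admission" / "month" / "control"
    tree: PhyloTree
    metadata: SampleMetadata
    responses: dict[str, ResponsePanel]  # "admission" / "month"
    ground_truth: GroundTruth
    config: CohortConfig


def generate_tree(n_leaves: int, seed: int | None = None,
                  names: list[str] | None = None) -> PhyloTree:
    """Random rooted binary tree with exponential branch lengths."""
    if n_leaves < 2:
        raise ValidationError("a tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"Genus{i:03d}" for i in range(1, n_leaves + 1)]
    nodes = [TreeNode(name=n, length=float(rng.exponential(0.1)))
             for n in names]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(length=float(rng.exponential(0.1)), children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


def sample_counts(component_params, n_samples: int, depths,
                  seed: int | None = None,
                  sample_ids: list[str] | None = None,
                  genus_names: list[str] | None = None) -> CountTable:
    """Draw Dirichlet-multinomial count vectors from one metacommunity."""
    alpha = np.asarray(component_params, dtype=float)
    if (alpha <= 0).any():
        raise ValidationError("Dirichlet parameters must be positive")
    depths = np.broadcast_to(np.asarray(depths, dtype=int), (n_samples,))
    if (depths < 1).any():
        raise ValidationError("read depths must be >= 1")
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet(alpha, size=n_samples)
    counts = np.array([rng.multinomial(d, p) for d, p in zip(depths, probs)])
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n_samples)]
    if genus_names is None:
        genus_names = [f"Genus{i:03d}" for i in range(1, alpha.size + 1)]
    return CountTable(sample_ids, genus_names, counts)


def generate_responses(ordination_axes: np.ndarray, coupling: np.ndarray,
                       noise_sd, seed: int | None = None,
                       sample_ids: list[str] | None = None,
                       analytes: pd.DataFrame | None = None):
    """Analyte panel as a linear function of ordination axes plus noise.

    Each analyte is ``coupling_row . axes + N(0, noise_sd)``, shifted
    upward (4 total-sd baseline) so values are non-negative; residual
    negatives are clipped at 0 and the clipped fraction logged.

    Returns ``(panel, info)`` where ``info`` records, per analyte, the
    empirical signal variance and the true explained-variance fraction
    var(signal) / (var(signal) + noise_sd^2).
    """
    axes = np.asarray(ordination_axes, dtype=float)
    coupling = np.asarray(coupling, dtype=float)
    if axes.ndim != 2 or coupling.ndim != 2 or coupling.shape[1] != axes.shape[1]:
        raise ValidationError("coupling columns must match ordination axes")
    n, n_analytes = axes.shape[0], coupling.shape[0]
    noise_sd = np.broadcast_to(np.asarray(noise_sd, dtype=float), (n_analytes,))
    rng = np.random.default_rng(seed)
    signal = axes @ coupling.T
    noise = rng.normal(0.0, 1.0, size=(n, n_analytes)) * noise_sd
    raw = signal + noise
    total_sd = np.sqrt(signal.var(axis=0, ddof=1) + noise_sd ** 2)
    baseline = 4.0 * np.where(total_sd > 0, total_sd, 1.0)
    values = raw + baseline
    clipped = values < 0
    if clipped.any():
        logger.info("clipped %.3f%% of analyte values at the 0 floor",
                    100.0 * clipped.mean())
        values = np.clip(values, 0.0, None)
    if sample_ids is None:
        sample_ids = [f"s{i:04d}" for i in range(n)]
    if analytes is None:
        analytes = pd.DataFrame({"stimulus": "LPS", "cell_type": "monocyte"},
                                index=[f"analyte{i}" for i in range(n_analytes)])
    panel = ResponsePanel(pd.DataFrame(values, index=sample_ids,
                                       columns=analytes.index), analytes)
    sig_var = signal.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        frac = np.where(sig_var + noise_sd ** 2 > 0,
                        sig_var / (sig_var + noise_sd ** 2), 0.0)
    info = pd.DataFrame({"signal_var": sig_var, "noise_sd": noise_sd,
                         "true_explained": frac}, index=analytes.index)
    return panel, info


def _standardize(axes: np.ndarray) -> np.ndarray:
    sd = axes.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (axes - axes.mean(axis=0)) / sd


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate one full synthetic cohort with ground truth.

    Patients keep their metacommunity (A = undisrupted, B = disrupted)
    across timepoints; the follow-up set is a seeded subset of the
    admission patients; controls are drawn from the undisrupted
    metacommunity.  Admission analyte panels use zero coupling to the
    community axes; month panels use the configured coupling.
    """
    config = config if config is not None else CohortConfig()
    streams = np.random.SeedSequence(config.seed).spawn(8)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in streams]
    tree = generate_tree(config.n_genera, seed=seeds[0], names=config.genus_names)

    rng = np.random.default_rng(seeds[1])
    n_b = int(round(config.disrupted_fraction * config.n_admission))
    components = np.array(["A"] * (config.n_admission - n_b) + ["B"] * n_b)
    rng.shuffle(components)
    patients = [f"P{i + 1:03d}" for i in range(config.n_admission)]
    retained = sorted(rng.choice(config.n_admission, size=config.n_month,
                                 replace=False))

    def draw_table(ids, comps, seed):
        local = np.random.default_rng(seed)
        depths = np.maximum(np.exp(local.normal(
            config.depth_log_mean, config.depth_log_sd, len(ids))).astype(int), 100)
        rows, table_rng = [], np.random.default_rng(seed + 1)
        for comp, depth in zip(comps, depths):
            alpha = config.alpha_a if comp == "A" else config.alpha_b
            p = table_rng.dirichlet(alpha)
            rows.append(table_rng.multinomial(depth, p))
        return CountTable(ids, list(config.genus_names), np.asarray(rows))

    adm_ids = [f"{p}_adm" for p in patients]
    mon_ids = [f"{patients[i]}_mon" for i in retained]
    ctl_ids = [f"C{i + 1:03d}" for i in range(config.n_controls)]
    counts = {"admission": draw_table(adm_ids, components, seeds[2])}
    if mon_ids:
        counts["month"] = draw_table(mon_ids, components[retained], seeds[3])
    if ctl_ids:
        counts["control"] = draw_table(ctl_ids, ["A"] * config.n_controls,
                                       seeds[4])

    comp_series = pd.Series(
        dict(zip(adm_ids, components))
        | dict(zip(mon_ids, components[retained]))
        | dict.fromkeys(ctl_ids, "A"))

    meta_rng = np.random.default_rng(seeds[5])
    meta_rows = {}
    for pid, sample in zip(patients, adm_ids):
        meta_rows[sample] = _random_clinical(meta_rng, group="CAP",
                                             timepoint="admission")
    for i, sample in zip(retained, mon_ids):
        row = dict(meta_rows[f"{patients[i]}_adm"])
        row["timepoint"] = "month"
        meta_rows[sample] = row
    for sample in ctl_ids:
        meta_rows[sample] = _random_clinical(meta_rng, group="control",
                                             timepoint="none")
    metadata = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))

    responses, coupling_by_tp, explained_by_tp = {}, {}, {}
    for tp, resp_seed, c in (("admission", seeds[6], np.zeros_like(config.coupling)),
                             ("month", seeds[7], config.coupling)):
        if tp not in counts:
            continue
        table = counts[tp]
        dm = unifrac(table, tree, weighted=True, normalized=True)
        axes = pcoa(dm, config.n_axes).coordinates
        std_axes = _standardize(axes)
        panel, info = generate_responses(std_axes, c, config.noise_sd,
                                         seed=resp_seed,
                                         sample_ids=table.sample_ids,
                                         analytes=config.analytes)
        responses[tp] = panel
        coupling_by_tp[tp] = c
        explained_by_tp[tp] = info["true_explained"]

    truth = GroundTruth(components=comp_series, coupling=coupling_by_tp,
                        true_explained=explained_by_tp)
    return Cohort(counts=counts, tree=tree, metadata=metadata,
                  responses=responses, ground_truth=truth, config=config)


def _random_clinical(rng: np.random.Generator, group: str, timepoint: str) -> dict:
    is_cap = group == "CAP"
    return {
        "group": group,
        "timepoint": timepoint,
        "age": float(np.clip(rng.normal(70 if is_cap else 65, 10), 20, 95)),
        "sex": "male" if rng.random() < 0.6 else "female",
        "copd": bool(rng.random() < (0.25 if is_cap else 0.05)),
        "cardiovascular": bool(rng.random() < (0.35 if is_cap else 0.15)),
        "diabetes": bool(rng.random() < 0.2),
        "malignancy": bool(rng.random() < (0.15 if is_cap else 0.05)),
        "immunosuppressed": bool(rng.random() < (0.1 if is_cap else 0.02)),
        "gastrointestinal": bool(rng.random() < 0.1),
        "renal": bool(rng.random() < 0.1),
        "prior_antibiotics": bool(rng.random() < (0.3 if is_cap else 0.05)),
    }
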