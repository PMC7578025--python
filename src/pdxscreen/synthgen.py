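"""Synthetic screens with planted ground truth.

Generates everything the downstream pipeline consumes -- raw 384-well
plates, an expression matrix with pathway modules, gene sets, subtype
labels, and binary mutation calls -- from a single seeded configuration,
together with a :class:`SyntheticTruth` record of every planted parameter
so recovery can be judged exactly.

Luminescence model: a drug well reads
``vehicle_mean * (1 - FA_true(dose)) * lognormal(cv)`` where ``FA_true``
comes from the planted 4PL for that drug-model pair, with a per-replicate
log10 AC50 perturbation so the minimum significance ratio has a known
analytic expectation.  The multiplicative log-normal factor has mean 1 and
the configured coefficient of variation.  Edge effects, drift, and
carryover are not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm

from .doseresp import fourpl, fourpl_auc
from .errors import CapacityError, ConfigError
from .platecore import Plate

__all__ = [
    "SyntheticConfig", "SyntheticTruth",
    "generate_screen", "generate_expression", "generate_labels",
    "DEFAULT_SUBTYPE_COUNTS",
]

#: Cohort mirror: 2 BL1, 4 BL2, 1 IM, 4 LAR, 4 M, 1 UNS = 16 models.
DEFAULT_SUBTYPE_COUNTS = {"BL1": 2, "BL2": 4, "IM": 1,
                          "LAR": 4, "M": 4, "UNS": 1}

_ROWS = "ABCDEFGHIJKLMNOP"
_WELLS_PER_PLATE = 384


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic screen, expression, and label generators.

    Control-well defaults (vehicle mean 10,000 RLU at CV 5%; positive
    control 95% kill at CV 10%) are chosen so the expected Z-prime is
    about 0.83, comfortably above the 0.75 QC bound the pipeline is
    validated against.
    """

    n_models: int = 16
    n_drugs: int = 24
    doses_uM: Tuple[float, ...] = (10.0, 1.0, 0.1)
    n_replicates: int = 3
    dmso_wells_per_plate: int = 16
    poscon_wells_per_plate: int = 16
    luminescence_mean_vehicle: float = 10_000.0
    cv_vehicle: float = 0.05
    poscon_kill_fraction: float = 0.95
    cv_poscon: float = 0.10
    replicate_log10_potency_sd: float = 0.05
    max_plates_per_model: int = 4
    # expression side
    n_genes: int = 2000
    n_gene_sets: int = 20
    gene_set_size: int = 25
    expr_noise_sd: float = 0.30  # log2 units per gene x sample
    # labels
    subtype_counts: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_COUNTS))
    n_background_mutation_genes: int = 5
    # planted associations
    planted_selective_drugs: Tuple[Tuple[str, str, float], ...] = (
        ("D013", "M", 0.3),)
    planted_pathway_drug_pairs: Tuple[Tuple[str, str, float], ...] = (
        ("SET01", "D014", 0.8),)
    planted_mutation_drug_pair: Optional[Tuple[str, str, float]] = (
        "TP53", "D015", 0.3)
    planted_moa_groups: Tuple[Tuple[str, Tuple[str, ...]], ...] = (
        ("anthracycline_like", ("D016", "D017", "D018")),)
    seed: int = 0

    def validate(self) -> None:
        doses = tuple(self.doses_uM)
        if any(d <= 0 for d in doses):
            raise ConfigError("doses must be strictly positive")
        if list(doses) != sorted(doses, reverse=True):
            raise ConfigError("doses must be sorted descending")
        if len(set(doses)) != len(doses):
            raise ConfigError("doses must be distinct")
        if not (0 < self.cv_vehicle < 1) or not (0 <= self.cv_poscon < 1):
            raise ConfigError("CVs must lie in (0, 1)")
        if not (0 < self.poscon_kill_fraction <= 1):
            raise ConfigError("poscon_kill_fraction must lie in (0, 1]")
        if self.n_replicates not in (3, 4):
            raise ConfigError("n_replicates must be 3 or 4")
        for name in ("n_models", "n_drugs", "dmso_wells_per_plate",
                     "poscon_wells_per_plate", "n_genes", "n_gene_sets",
                     "gene_set_size"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if sum(self.subtype_counts.values()) != self.n_models:
            raise ConfigError(
                f"subtype counts sum to {sum(self.subtype_counts.values())}"
                f", expected n_models={self.n_models}")
        if self.gene_set_size > self.n_genes:
            raise ConfigError("gene_set_size exceeds n_genes")

    @property
    def model_ids(self) -> List[str]:
        return [f"M{i + 1:02d}" for i in range(self.n_models)]

    @property
    def drug_ids(self) -> List[str]:
        return [f"D{i + 1:03d}" for i in range(self.n_drugs)]

    @property
    def dose_range_uM(self) -> Tuple[float, float]:
        return (min(self.doses_uM), max(self.doses_uM))


@dataclass
class SyntheticTruth:
    """Planted parameters behind one synthetic dataset."""

    params: pd.DataFrame          # drug_id, model_id, bottom, top, log10_ac50, hill
    true_auc: pd.DataFrame        # models x drugs
    drug_class: Dict[str, str]    # inactive | graded | pan_active | flat
    moa_class: Dict[str, str]     # drug -> mechanism label (planted groups)
    planted: dict
    subtypes: pd.Series           # model -> subtype
    mutations: pd.DataFrame       # models x genes, {0, 1}
    dose_range_uM: Tuple[float, float]
    seed: int

    def curve(self, drug_id: str, model_id: str) -> dict:
        row = self.params[(self.params["drug_id"] == drug_id)
                          & (self.params["model_id"] == model_id)]
        if len(row) != 1:
            raise KeyError(f"no unique truth record for "
                           f"({drug_id}, {model_id})")
        return row.iloc[0][["bottom", "top", "log10_ac50", "hill"]].to_dict()


def _rngs(seed: int):
    """Fixed-order child generators: labels, truth, plate noise, expression."""
    children = np.random.SeedSequence(seed).spawn(4)
    return tuple(np.random.default_rng(c) for c in children)


def _normal_scores(n: int, rng: np.random.Generator) -> np.ndarray:
    """Randomly permuted Blom normal scores, standardized to mean 0 / sd 1.

    Bounded and exactly standardized, so planted effects built from them
    stay inside [0, 1] after affine mapping.
    """
    ranks = rng.permutation(n) + 1
    z = norm.ppf((ranks - 0.375) / (n + 0.25))
    z = z - z.mean()
    return z / z.std()


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative log-normal noise with mean 1 and the given CV."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-0.5 * sigma2, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def generate_labels(config: SyntheticConfig):
    """Subtype table and binary mutation table with planted carriers.

    Returns ``(subtypes, mutations)``: a Series mapping model to subtype
    and a models x genes {0,1} frame.  Deterministic given the seed; the
    screen generator derives the same labels internally so planted
    subtype- and mutation-linked drug effects are consistent.
    """
    config.validate()
    rng = _rngs(config.seed)[0]
    models = config.model_ids

    labels = [s for s, k in config.subtype_counts.items() for _ in range(k)]
    order = rng.permutation(config.n_models)
    subtypes = pd.Series([labels[i] for i in order], index=models,
                         name="subtype")
    subtypes.index.name = "model_id"

    genes = []
    cols = {}
    if config.planted_mutation_drug_pair is not None:
        gene, _drug, _shift = config.planted_mutation_drug_pair
        carriers = rng.choice(config.n_models,
                              size=math.ceil(config.n_models / 2),
                              replace=False)
        col = np.zeros(config.n_models, dtype=int)
        col[carriers] = 1
        genes.append(gene)
        cols[gene] = col
    for i in range(config.n_background_mutation_genes):
        g = f"MUT{i + 1:02d}"
        genes.append(g)
        cols[g] = rng.binomial(1, rng.uniform(0.2, 0.6),
                               size=config.n_models)
    mutations = pd.DataFrame(cols, index=models, columns=genes)
    mutations.index.name = "model_id"
    return subtypes, mutations


# ---------------------------------------------------------------------------
# truth (planted curves)
# ---------------------------------------------------------------------------

def _plant_truth(config: SyntheticConfig, rng: np.random.Generator,
                 subtypes: pd.Series, mutations: pd.DataFrame):
    models = config.model_ids
    drugs = config.drug_ids
    n_m = config.n_models
    lo, hi = (math.log10(d) for d in config.dose_range_uM)

    n_inactive = max(1, round(0.3 * config.n_drugs))
    n_pan = max(1, round(0.25 * config.n_drugs))
    classes = {}
    for i, d in enumerate(drugs):
        if i < n_inactive:
            classes[d] = "inactive"
        elif i >= config.n_drugs - n_pan:
            classes[d] = "pan_active"
        else:
            classes[d] = "graded"

    # per-drug base curves + per-model variation
    records = {}
    for d in drugs:
        cls = classes[d]
        if cls == "inactive":
            top = rng.uniform(0.0, 0.05)
            base = dict(bottom=0.0, top=top,
                        log10_ac50=rng.uniform(-0.5, 0.5), hill=1.0)
            jitter_sd = 0.0
        elif cls == "pan_active":
            base = dict(bottom=0.0, top=rng.uniform(0.9, 1.0),
                        log10_ac50=rng.uniform(lo - 0.6, lo - 0.1),
                        hill=rng.uniform(1.0, 3.0))
            jitter_sd = 0.10
        else:
            base = dict(bottom=0.0, top=rng.uniform(0.8, 1.0),
                        log10_ac50=rng.uniform(lo + 0.3, hi - 0.3),
                        hill=rng.uniform(0.8, 2.5))
            jitter_sd = 0.15
        per_model = []
        for _m in models:
            p = dict(base)
            p["log10_ac50"] = float(
                np.clip(base["log10_ac50"] + rng.normal(0.0, jitter_sd),
                        lo - 1.0, hi + 1.0))
            per_model.append(p)
        records[d] = per_model

    planted: dict = {"selective": [], "pathway": [], "mutation": None,
                     "moa_groups": {}}
    moa_class = {}

    # mechanism groups: member drugs share one base profile across models
    for name, members in config.planted_moa_groups:
        missing = [m for m in members if m not in records]
        if missing:
            raise ConfigError(f"moa group {name!r} names unknown drugs "
                              f"{missing}")
        shared = []
        top = rng.uniform(0.8, 1.0)
        hill = rng.uniform(1.0, 2.0)
        center = rng.uniform(lo + 0.3, hi - 0.3)
        for _m in models:
            shared.append(dict(bottom=0.0, top=top,
                               log10_ac50=float(np.clip(
                                   center + rng.normal(0.0, 0.4),
                                   lo - 1.0, hi + 1.0)),
                               hill=hill))
        for m in members:
            records[m] = [dict(p) for p in shared]
            classes[m] = "graded"
            moa_class[m] = name
        planted["moa_groups"][name] = list(members)

    # subtype-selective drugs: top shifted in target-subtype models
    for drug, subtype, effect in config.planted_selective_drugs:
        if drug not in records:
            raise ConfigError(f"planted selective drug {drug!r} unknown")
        if subtype not in set(subtypes):
            raise ConfigError(f"planted subtype {subtype!r} not in labels")
        base_top = 0.45
        for i, m in enumerate(models):
            boost = effect if subtypes[m] == subtype else 0.0
            records[drug][i] = dict(
                bottom=0.0, top=min(1.0, base_top + boost),
                log10_ac50=float(rng.normal(0.5 * (lo + hi), 0.05)),
                hill=4.0)
        classes[drug] = "graded"
        planted["selective"].append(
            {"drug": drug, "subtype": subtype, "effect": effect})

    # pathway-correlated drugs: flat curves, AUC = a exactly by construction
    for set_name, drug, r in config.planted_pathway_drug_pairs:
        if drug not in records:
            raise ConfigError(f"planted pathway drug {drug!r} unknown")
        z = _normal_scores(n_m, rng)
        a = 0.5 + 0.18 * z
        for i, m in enumerate(models):
            records[drug][i] = dict(bottom=float(a[i]), top=float(a[i]),
                                    log10_ac50=0.0, hill=1.0)
        classes[drug] = "flat"
        planted["pathway"].append(
            {"set": set_name, "drug": drug, "target_r": r,
             "auc_scores": {m: float(v) for m, v in zip(models, a)}})

    # mutation-linked drug: flat curves, carrier AUC shifted by exactly the
    # configured amount
    if config.planted_mutation_drug_pair is not None:
        gene, drug, shift = config.planted_mutation_drug_pair
        if drug not in records:
            raise ConfigError(f"planted mutation drug {drug!r} unknown")
        carriers = mutations[gene].to_numpy()
        base_a = 0.4
        for i, m in enumerate(models):
            a = base_a + (shift if carriers[i] else 0.0)
            records[drug][i] = dict(bottom=float(a), top=float(a),
                                    log10_ac50=0.0, hill=1.0)
        classes[drug] = "flat"
        planted["mutation"] = {"gene": gene, "drug": drug, "shift": shift}

    rows = []
    for d in drugs:
        for m, p in zip(models, records[d]):
            rows.append({"drug_id": d, "model_id": m, **p})
    params = pd.DataFrame(rows)

    auc_vals = {
        d: [fourpl_auc(p["bottom"], p["top"], p["log10_ac50"], p["hill"],
                       config.dose_range_uM) for p in records[d]]
        for d in drugs
    }
    true_auc = pd.DataFrame(auc_vals, index=models)
    true_auc.index.name = "model_id"
    return params, true_auc, classes, moa_class, planted


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def _plate_capacity(config: SyntheticConfig) -> int:
    cap = (_WELLS_PER_PLATE - config.dmso_wells_per_plate
           - config.poscon_wells_per_plate)
    if cap <= 0:
        raise CapacityError(
            "control wells alone exceed the 384-well plate")
    return cap


def generate_screen(config: SyntheticConfig):
    """Simulate raw plates for every model; returns ``(plates, truth)``.

    Every model's screen contains all drugs at all doses x replicates plus
    DMSO and positive-control wells on each plate.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    labels_unused, truth_rng, noise_rng, _ = _rngs(config.seed)
    subtypes, mutations = generate_labels(config)
    params, true_auc, classes, moa_class, planted = _plant_truth(
        config, truth_rng, subtypes, mutations)

    cap = _plate_capacity(config)
    n_doses = len(config.doses_uM)
    drug_wells = config.n_drugs * n_doses * config.n_replicates
    n_plates = math.ceil(drug_wells / cap)
    if n_plates > config.max_plates_per_model:
        raise CapacityError(
            f"{drug_wells} drug wells need {n_plates} plates/model, "
            f"limit is {config.max_plates_per_model} "
            f"({_WELLS_PER_PLATE} wells each)")

    all_wells = [f"{r}{c:02d}" for r in _ROWS for c in range(1, 25)]
    curve_lut = {(r.drug_id, r.model_id): r
                 for r in params.itertuples(index=False)}

    plates: List[Plate] = []
    for model in config.model_ids:
        # per-replicate potency jitter, shared across the doses of a replicate
        jitter = {
            (d, rep): noise_rng.normal(0.0, config.replicate_log10_potency_sd)
            for d in config.drug_ids for rep in range(1, config.n_replicates + 1)
        }
        jobs = [(d, dose, rep) for d in config.drug_ids
                for dose in config.doses_uM
                for rep in range(1, config.n_replicates + 1)]
        for p_idx in range(n_plates):
            chunk = jobs[p_idx * cap:(p_idx + 1) * cap]
            rows = []
            cursor = 0
            for _ in range(config.dmso_wells_per_plate):
                rlu = (config.luminescence_mean_vehicle
                       * _lognormal_factor(noise_rng, config.cv_vehicle, None))
                rows.append((all_wells[cursor], "DMSO", "", np.nan, 0,
                             float(rlu)))
                cursor += 1
            pos_mean = (config.luminescence_mean_vehicle
                        * (1.0 - config.poscon_kill_fraction))
            for _ in range(config.poscon_wells_per_plate):
                rlu = pos_mean * _lognormal_factor(noise_rng,
                                                   config.cv_poscon, None)
                rows.append((all_wells[cursor], "POSCON", "", np.nan, 0,
                             float(rlu)))
                cursor += 1
            for drug, dose, rep in chunk:
                c = curve_lut[(drug, model)]
                fa = float(fourpl(math.log10(dose), c.bottom, c.top,
                                  c.log10_ac50 + jitter[(drug, rep)],
                                  c.hill))
                mean_rlu = config.luminescence_mean_vehicle * max(0.0, 1.0 - fa)
                rlu = mean_rlu * _lognormal_factor(noise_rng,
                                                   config.cv_vehicle, None)
                rows.append((all_wells[cursor], "DRUG", drug, float(dose),
                             rep, float(rlu)))
                cursor += 1
            for w in all_wells[cursor:]:
                rows.append((w, "EMPTY", "", np.nan, 0, 0.0))
            wells = pd.DataFrame(
                rows, columns=["well", "role", "drug_id", "dose_uM",
                               "replicate", "rlu"])
            plates.append(Plate(barcode=f"{model}-{p_idx + 1:02d}",
                                wells=wells))

    truth = SyntheticTruth(
        params=params, true_auc=true_auc, drug_class=classes,
        moa_class=moa_class, planted=planted, subtypes=subtypes,
        mutations=mutations, dose_range_uM=config.dose_range_uM,
        seed=config.seed)
    return plates, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(config: SyntheticConfig, truth: SyntheticTruth):
    """Expression matrix (genes x models, TPM-like) plus gene sets.

    For each planted (gene set, drug, r) pair the member genes share a
    latent signal built from the drug's true AUC profile: the signal is
    an exact in-sample mixture ``r * z(AUC) + sqrt(1 - r^2) * eta`` with
    ``eta`` orthogonalized against ``z(AUC)``, so the module-mean
    correlation with true AUC equals ``r`` by construction and the
    realized pathway-score correlation lands close to target.

    Returns ``(expr, gene_sets)`` where ``gene_sets`` maps set name to a
    list of member genes (write with :func:`pdxscreen.pathways.write_gmt`).
    """
    config.validate()
    rng = _rngs(config.seed)[3]
    models = config.model_ids
    n_m = config.n_models
    genes = [f"G{i + 1:04d}" for i in range(config.n_genes)]

    planted_pairs = list(config.planted_pathway_drug_pairs)
    n_planted = len(planted_pairs)
    need = n_planted * config.gene_set_size
    if need > config.n_genes:
        raise ConfigError("planted modules need more genes than n_genes")

    # carve disjoint planted modules off the front of the gene list
    planted_members = {}
    offset = 0
    for set_name, _drug, _r in planted_pairs:
        planted_members[set_name] = genes[offset:offset + config.gene_set_size]
        offset += config.gene_set_size
    background_pool = genes[offset:]

    log2e = np.tile(rng.normal(5.0, 1.0, size=config.n_genes)[:, None],
                    (1, n_m))
    if config.expr_noise_sd > 0:
        log2e = log2e + rng.normal(0.0, config.expr_noise_sd,
                                   size=(config.n_genes, n_m))

    gene_index = {g: i for i, g in enumerate(genes)}
    for set_name, drug, r in planted_pairs:
        if drug not in truth.true_auc.columns:
            raise ConfigError(f"planted drug {drug!r} not in truth")
        auc = truth.true_auc[drug].to_numpy(float)
        sd = auc.std()
        if sd == 0:
            raise ConfigError(
                f"planted drug {drug!r} has constant true AUC; "
                "cannot target a correlation")
        z = (auc - auc.mean()) / sd
        eta = rng.normal(size=n_m)
        eta = eta - eta.mean()
        eta = eta - (eta @ z) / (z @ z) * z
        nrm = eta.std()
        eta = eta / nrm if nrm > 0 else np.zeros(n_m)
        signal = r * z + math.sqrt(max(0.0, 1.0 - r * r)) * eta
        for g in planted_members[set_name]:
            scale = rng.uniform(1.5, 2.5)
            log2e[gene_index[g], :] += scale * signal

    expr = pd.DataFrame(2.0 ** log2e, index=genes, columns=models)
    expr.index.name = "gene_id"

    gene_sets: Dict[str, List[str]] = {}
    for i in range(config.n_gene_sets):
        name = f"SET{i + 1:02d}"
        if name in planted_members:
            gene_sets[name] = list(planted_members[name])
        else:
            picks = rng.choice(len(background_pool), size=config.gene_set_size,
                               replace=False)
            gene_sets[name] = [background_pool[j] for j in sorted(picks)]
    # planted sets referenced by names outside SETxx range
    for set_name, members in planted_members.items():
        gene_sets.setdefault(set_name, list(members))
    return expr, gene_sets
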