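"""Seeded synthetic cohorts with the correlation structure of the study design.

The generator emulates a whole-lung expression study: two phenotype groups
(case/control), paired upper/lower-lobe samples that share a patient (and
hence a patient effect inducing within-pair correlation), a biopsy-vs-explant
batch split within cases, and a second microarray platform related to the
first by a many-by-many feature mapping plus per-feature affine distortion.

All randomness flows through named substreams spawned from one seed, so that
changing e.g. the number of noise draws never perturbs baseline draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, PhenotypeTable
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "FeatureMapping",
    "simulate_cohort",
    "simulate_second_platform",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic training/validation cohort.

    Defaults are sized to the study cohort: 11 cases (6 biopsy / 5 explant,
    6 with upper/lower lobe pairs) and 6 controls; log2-scale baseline
    ~ Normal(7, 1.5^2) as typical of RMA-summarized arrays; 150 truly
    differential features with a 1.5 log2-unit shift; a 1.0 log2-unit
    batch shift on 100 features for explants; within-pair residual
    correlation 0.7.
    """

    n_features: int = 2000
    frac_annotated: float = 0.9
    n_cases: int = 11
    n_controls: int = 6
    frac_paired_lobes: float = 6 / 11
    frac_explant: float = 5 / 11
    n_diff: int = 150
    effect_size: float = 1.5
    n_batch: int = 100
    batch_effect: float = 1.0
    within_patient_rho: float = 0.7
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_annotated", "frac_paired_lobes", "frac_explant",
                     "within_patient_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_diff > self.n_features:
            raise ValueError("n_diff exceeds n_features")
        if self.n_batch > self.n_features:
            raise ValueError("n_batch exceeds n_features")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


@dataclass
class SimulationTruth:
    """Ground truth of a simulated cohort."""

    diff_features: dict[str, float]   # feature_id -> signed log2 effect
    batch_features: list[str]
    latent_class: dict[str, int]      # sample_id -> 0/1


@dataclass
class FeatureMapping:
    """Links between training-platform and validation-platform features."""

    links: set[tuple[str, str]] = field(default_factory=set)
    provenance: str = "synthetic"

    def train_features(self) -> set[str]:
        return {t for t, _ in self.links}

    def val_features_for(self, train_id: str) -> list[str]:
        return sorted(v for t, v in self.links if t == train_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.links),
                            columns=["train_id", "val_id"])


def _substreams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_cohort(config: SimulationConfig, *,
                    n_cases: int | None = None,
                    n_controls: int | None = None,
                    frac_paired_lobes: float | None = None,
                    frac_explant: float | None = None,
                    cohort_seed: int | None = None,
                    sample_prefix: str = "",
                    ) -> tuple[ExpressionMatrix, PhenotypeTable, SimulationTruth]:
    """Draw one synthetic cohort.

    Model per feature g and sample s:
      x[g, s] = baseline_g + delta_g * 1[case] + gamma * 1[explant & g batch]
                + a[patient(s), g] + e[g, s]
    where a is a per-(patient, feature) effect shared by lobe pairs with
    variance tau^2 = rho/(1-rho) * sigma^2, and e is iid Normal(0, sigma^2);
    a lobe pair therefore has residual correlation rho per feature.

    Feature-level truth (baseline, differential effects, batch set,
    annotation) is derived from ``config.seed`` alone, while patients and
    noise use ``cohort_seed`` (default: config.seed).  Calling again with a
    different ``cohort_seed`` and its own sizes therefore yields an
    independent cohort from the *same* generative truth — how validation
    cohorts are produced.
    """
    config.validate()
    c = config
    # feature-truth streams keyed by config.seed; sample streams by cohort
    # seed, at disjoint spawn keys so the two never collide
    truth_children = np.random.SeedSequence(c.seed).spawn(3)
    cohort_children = np.random.SeedSequence(
        c.seed if cohort_seed is None else int(cohort_seed)).spawn(6)[3:]
    rngs = {
        "baseline": np.random.default_rng(truth_children[0]),
        "effects": np.random.default_rng(truth_children[1]),
        "annotation": np.random.default_rng(truth_children[2]),
        "design": np.random.default_rng(cohort_children[0]),
        "patient": np.random.default_rng(cohort_children[1]),
        "noise": np.random.default_rng(cohort_children[2]),
    }
    n_cases = c.n_cases if n_cases is None else int(n_cases)
    n_controls = c.n_controls if n_controls is None else int(n_controls)
    f_paired = (c.frac_paired_lobes if frac_paired_lobes is None
                else float(frac_paired_lobes))
    f_explant = c.frac_explant if frac_explant is None else float(frac_explant)

    features = [f"AFFX{g:06d}" for g in range(c.n_features)]

    # design: which cases are paired / explant
    n_paired = int(round(f_paired * n_cases))
    n_explant = int(round(f_explant * n_cases))
    order = rngs["design"].permutation(n_cases)
    paired = set(order[:n_paired])
    explant = set(rngs["design"].permutation(n_cases)[:n_explant])

    rows = []
    sample_patient: list[str] = []
    for i in range(n_cases):
        pat = f"{sample_prefix}SIMP{i + 1:03d}"
        stype = "explant" if i in explant else "biopsy"
        lobes = ["upper", "lower"] if i in paired else ["upper"]
        for lobe in lobes:
            sid = f"{sample_prefix}Case{i + 1:03d}{'U' if lobe == 'upper' else 'L'}"
            rows.append(dict(sample_id=sid, phenotype=1, patient_id=pat,
                             lobe=lobe, sample_type=stype))
            sample_patient.append(pat)
    for i in range(n_controls):
        pat = f"{sample_prefix}SIMC{i + 1:03d}"
        sid = f"{sample_prefix}Ctrl{i + 1:03d}"
        rows.append(dict(sample_id=sid, phenotype=0, patient_id=pat,
                         lobe="unknown", sample_type="control"))
        sample_patient.append(pat)
    pheno = PhenotypeTable(pd.DataFrame(rows))
    sample_ids = pheno.sample_ids
    n_samples = len(sample_ids)
    y = pheno.y()
    is_explant = (pheno.table["sample_type"] == "explant").to_numpy()

    baseline = rngs["baseline"].normal(c.baseline_mean, c.baseline_sd,
                                       size=c.n_features)

    eff_rng = rngs["effects"]
    diff_idx = eff_rng.choice(c.n_features, size=c.n_diff, replace=False)
    signs = eff_rng.choice([-1.0, 1.0], size=c.n_diff)
    delta = np.zeros(c.n_features)
    delta[diff_idx] = signs * c.effect_size
    batch_idx = eff_rng.choice(c.n_features, size=c.n_batch, replace=False)
    gamma = np.zeros(c.n_features)
    gamma[batch_idx] = c.batch_effect

    rho = c.within_patient_rho
    tau = c.noise_sd * np.sqrt(rho / (1.0 - rho)) if rho < 1.0 else None
    if tau is None:
        raise ValueError("within_patient_rho must be < 1")
    patients = sorted(set(sample_patient))
    pat_eff = {p: rngs["patient"].normal(0.0, tau, size=c.n_features)
               for p in patients}

    noise = rngs["noise"].normal(0.0, c.noise_sd,
                                 size=(c.n_features, n_samples))

    X = np.empty((c.n_features, n_samples))
    for j in range(n_samples):
        X[:, j] = (baseline + delta * y[j] + gamma * is_explant[j]
                   + pat_eff[sample_patient[j]] + noise[:, j])

    n_ann = int(round(c.frac_annotated * c.n_features))
    ann_idx = set(rngs["annotation"].choice(c.n_features, size=n_ann,
                                            replace=False).tolist())
    annotation = {
        features[g]: ({f"GENE{g:06d}"} if g in ann_idx else set())
        for g in range(c.n_features)
    }

    expr = ExpressionMatrix(features, sample_ids, X, annotation)
    truth = SimulationTruth(
        diff_features={features[g]: float(delta[g]) for g in sorted(diff_idx)},
        batch_features=[features[g] for g in sorted(batch_idx)],
        latent_class={sid: int(lbl) for sid, lbl in zip(sample_ids, y)},
    )
    return expr, pheno, truth


def simulate_second_platform(
    X: ExpressionMatrix,
    map_spec: dict | None = None,
    distortion: dict | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, FeatureMapping]:
    """Re-measure a cohort on a second platform.

    Source features are partitioned into link classes: one-to-one,
    many-to-one (pairs of source features averaged into one new feature),
    one-to-many (one source feeding two new features) and dropped (no
    link, emulating unmapped probes).  Every new feature is an affine
    image ``scale * value + shift`` of its source signal plus Normal noise;
    its annotation is the union of the linked source features' gene IDs, so
    annotation-driven mapping recovers the simulated links.
    """
    spec = dict(frac_one_to_one=0.8, frac_many_to_one=0.1,
                frac_one_to_many=0.08, drop_frac=0.02)
    if map_spec:
        spec.update(map_spec)
    dist = dict(scale_sd=0.2, shift_sd=0.5, noise_sd=0.2)
    if distortion:
        dist.update(distortion)
    fracs = (spec["frac_one_to_one"], spec["frac_many_to_one"],
             spec["frac_one_to_many"], spec["drop_frac"])
    if any(f < 0 for f in fracs) or sum(fracs) > 1.0 + 1e-12:
        raise ValueError("mapping fractions must be nonnegative and sum to <= 1")

    rngs = _substreams(seed, ["assign", "affine", "noise"])
    n = X.n_features
    perm = rngs["assign"].permutation(n)
    n_m2o = 2 * (int(round(spec["frac_many_to_one"] * n)) // 2)
    n_o2m = int(round(spec["frac_one_to_many"] * n))
    n_drop = int(round(spec["drop_frac"] * n))
    m2o = perm[:n_m2o]
    o2m = perm[n_m2o:n_m2o + n_o2m]
    drop = set(perm[n_m2o + n_o2m:n_m2o + n_o2m + n_drop].tolist())
    o2o = perm[n_m2o + n_o2m + n_drop:]

    def affine(sig: np.ndarray) -> np.ndarray:
        scale = max(0.2, rngs["affine"].normal(1.0, dist["scale_sd"]))
        shift = rngs["affine"].normal(0.0, dist["shift_sd"])
        noise = (rngs["noise"].normal(0.0, dist["noise_sd"], size=sig.shape)
                 if dist["noise_sd"] > 0 else 0.0)
        return scale * sig + shift + noise

    new_feats: list[str] = []
    new_rows: list[np.ndarray] = []
    new_ann: dict[str, set[str]] = {}
    links: set[tuple[str, str]] = set()
    counter = 0

    def add_feature(sig: np.ndarray, sources: list[int]) -> None:
        nonlocal counter
        vid = f"AGIL{counter:06d}"
        counter += 1
        new_feats.append(vid)
        new_rows.append(affine(sig))
        genes: set[str] = set()
        for s in sources:
            tid = X.feature_ids[s]
            links.add((tid, vid))
            genes |= X.annotation.get(tid, set())
        new_ann[vid] = genes

    for g in sorted(o2o.tolist()):
        add_feature(X.values[g], [g])
    for a, b in zip(sorted(m2o.tolist())[0::2], sorted(m2o.tolist())[1::2]):
        add_feature(0.5 * (X.values[a] + X.values[b]), [a, b])
    for g in sorted(o2m.tolist()):
        add_feature(X.values[g], [g])
        add_feature(X.values[g], [g])

    X_val = ExpressionMatrix(new_feats, list(X.sample_ids),
                             np.vstack(new_rows), new_ann)
    return X_val, FeatureMapping(links=links)
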