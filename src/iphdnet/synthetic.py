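"""Seeded LINCS-like fixture generator with planted ground truth.

Emulates the shapes and metadata of the targeted assays the pipeline
consumes — a GCP-like histone-mark matrix (~60 combinatorial marks, 24 h),
a P100-like phosphopeptide matrix (~96 peptides at 3/6/24 h), vehicle
(DMSO) control columns and plate replicates — with planted structure at
both modelling stages: k balanced drug/histone modules giving the histone
fold changes a block pattern for the NMF stage, and a sparse linear
coefficient map B0 tying phosphoprotein fold changes to histone fold
changes for the PLSR stage.  Every quantity the tests need is returned in
the truth object; regeneration under the same seed is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_gct import AnalyteMatrix, PpiGraph

# Defaults mirror the assay the pipeline targets: 60 histone marks, 96
# phosphopeptides, 31 drugs, four signatures, measured at 3/6/24 h.
DEFAULT_N_HISTONES = 60
DEFAULT_N_PHOSPHO = 96
DEFAULT_N_DRUGS = 31
DEFAULT_K = 4
DEFAULT_EFFECT = 1.5  # log2 units
DEFAULT_SIGMA = 0.3  # log2 units
DEFAULT_TIMEPOINTS = (3.0, 6.0, 24.0)
DEFAULT_REPLICATES = 2
DEFAULT_B0_DENSITY = 0.05
BASELINE_MEAN = 8.0  # log2 abundance around which analytes sit
BASELINE_SD = 1.0
#: Fraction of the 24 h response already present at earlier time points.
TIME_RAMP = {3.0: 0.4, 6.0: 0.7, 24.0: 1.0}


@dataclass
class SyntheticTruth:
    """Planted ground truth plus the generated assay matrices."""

    gcp: AnalyteMatrix
    p100: AnalyteMatrix
    drug_modules: dict[str, str]
    histone_modules: dict[str, str]
    pair_signs: dict[tuple[str, str], int]
    B0: np.ndarray  # phospho x histone
    histone_ids: list[str] = field(default_factory=list)
    phospho_ids: list[str] = field(default_factory=list)
    drug_ids: list[str] = field(default_factory=list)
    k: int = DEFAULT_K
    effect: float = DEFAULT_EFFECT
    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def gcp_signal(self) -> np.ndarray:
        """Noiseless planted histone fold-change matrix (histones x drugs)."""
        out = np.zeros((len(self.histone_ids), len(self.drug_ids)))
        for j, d in enumerate(self.drug_ids):
            for i, h in enumerate(self.histone_ids):
                if self.drug_modules[d] == self.histone_modules[h]:
                    out[i, j] = self.pair_signs[(d, h)] * self.effect
        return out


def _partition(ids: list[str], k: int) -> dict[str, str]:
    # balanced round-robin module assignment c1..ck
    return {x: f"c{(i % k) + 1}" for i, x in enumerate(ids)}


def _sample_meta_row(sample_id, cell_line, pert, dose, t, rep, is_control):
    return {
        "sample_id": sample_id,
        "cell_line": cell_line,
        "perturbagen": pert,
        "dose": dose,
        "timepoint_h": float(t),
        "replicate": int(rep),
        "is_control": bool(is_control),
    }


def simulate_gcp_p100(
    n_histones: int = DEFAULT_N_HISTONES,
    n_phospho: int = DEFAULT_N_PHOSPHO,
    n_drugs: int = DEFAULT_N_DRUGS,
    k: int = DEFAULT_K,
    effect: float = DEFAULT_EFFECT,
    sigma: float = DEFAULT_SIGMA,
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS,
    replicates: int = DEFAULT_REPLICATES,
    b0_density: float = DEFAULT_B0_DENSITY,
    cell_line: str = "MCF7",
    seed: int = 0,
) -> SyntheticTruth:
    """Generate coupled GCP-like and P100-like matrices with planted truth.

    Drugs and histones are partitioned into ``k`` balanced modules; a
    within-module (drug, histone) pair gets a fold-change signal of
    +-``effect`` (direction drawn once per (module, histone), so every
    drug of a module moves a given mark the same way — the coherent
    response pattern a signature is), zero elsewhere, with independent
    Normal(0, sigma) noise per measured cell.  The P100 block is built so
    that at 24 h, phospho fold changes P satisfy GCP ~= P @ B0 for a
    sparse planted B0 (default 5% density); earlier time points carry a
    scaled-down response.  DMSO control columns at baseline and jittered
    replicates are included so the preprocessing stage is exercised for
    real.
    """
    if not 1 <= k <= min(n_histones, n_drugs):
        raise ValueError(f"k={k} outside [1, min(n_histones, n_drugs)]")
    if effect <= 0:
        raise ValueError("effect must be positive")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if not 0 < b0_density <= 1:
        raise ValueError("b0_density must be in (0, 1]")

    rng = np.random.default_rng(seed)
    histone_ids = [f"H3mark{i:02d}" for i in range(n_histones)]
    phospho_ids = [f"pP{i:03d}" for i in range(n_phospho)]
    drug_ids = [f"drug{j:02d}" for j in range(n_drugs)]

    drug_modules = _partition(drug_ids, k)
    histone_modules = _partition(histone_ids, k)

    # direction of each histone's response, shared by the drugs of its module
    histone_sign = {h: int(rng.choice([-1, 1])) for h in histone_ids}
    pair_signs = {
        (d, h): histone_sign[h]
        for d in drug_ids
        for h in histone_ids
        if drug_modules[d] == histone_modules[h]
    }

    truth = SyntheticTruth(
        gcp=None,  # type: ignore[arg-type]  (filled below)
        p100=None,  # type: ignore[arg-type]
        drug_modules=drug_modules,
        histone_modules=histone_modules,
        pair_signs=pair_signs,
        B0=np.zeros((n_phospho, n_histones)),
        histone_ids=histone_ids,
        phospho_ids=phospho_ids,
        drug_ids=drug_ids,
        k=k,
        effect=effect,
        sigma=sigma,
        seed=seed,
    )
    gcp_signal = truth.gcp_signal()  # histones x drugs, 24 h scale

    # sparse phospho->histone coefficient map; resample until full column
    # rank so the min-norm preimage reproduces the histone signal exactly
    for _attempt in range(20):
        mask = rng.random((n_phospho, n_histones)) < b0_density
        magnitudes = rng.uniform(0.5, 1.5, size=mask.shape)
        signs = rng.choice([-1.0, 1.0], size=mask.shape)
        B0 = np.where(mask, magnitudes * signs, 0.0)
        if np.linalg.matrix_rank(B0) == min(B0.shape):
            break
    truth.B0 = B0
    # phospho fold-change signal at 24 h: minimum-norm X with X @ B0 = GCP^T
    p100_signal_24 = gcp_signal.T @ np.linalg.pinv(B0)  # drugs x phospho

    gcp_baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_histones)
    p100_baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=n_phospho)

    def build_matrix(analyte_ids, analyte_type, baseline, signal_by_t, tps):
        cols, meta_rows = [], []
        for t in tps:
            for pert in ["DMSO", *drug_ids]:
                sig = (
                    np.zeros(len(analyte_ids))
                    if pert == "DMSO"
                    else signal_by_t(t)[:, drug_ids.index(pert)]
                )
                dose = "0" if pert == "DMSO" else "10uM"
                for rep in range(1, replicates + 1):
                    noise = rng.normal(0.0, sigma, size=len(analyte_ids))
                    cols.append(baseline + sig + noise)
                    meta_rows.append(
                        _sample_meta_row(
                            f"{cell_line}_{pert}_{t:g}h_r{rep}",
                            cell_line,
                            pert,
                            dose,
                            t,
                            rep,
                            pert == "DMSO",
                        )
                    )
        analyte_meta = pd.DataFrame(
            {
                "analyte_type": analyte_type,
                "parent_gene": [f"GENE_{a}" for a in analyte_ids],
            },
            index=pd.Index(analyte_ids, name="id"),
        )
        sample_meta = pd.DataFrame(meta_rows).set_index("sample_id")
        return AnalyteMatrix(np.column_stack(cols), analyte_meta, sample_meta)

    truth.gcp = build_matrix(
        histone_ids,
        "histone_mark",
        gcp_baseline,
        lambda t: TIME_RAMP.get(t, 1.0) * gcp_signal,
        (24.0,),  # chromatin profiled at 24 h only
    )
    truth.p100 = build_matrix(
        phospho_ids,
        "phosphopeptide",
        p100_baseline,
        lambda t: TIME_RAMP.get(t, 1.0) * p100_signal_24.T,
        tuple(float(t) for t in timepoints),
    )
    return truth


def simulate_plsr_system(
    n_samples: int = 60,
    n_predictors: int = 96,
    n_responses: int = 60,
    density: float = DEFAULT_B0_DENSITY,
    noise_sd: float = 0.5,
    coef_low: float = 0.75,
    coef_high: float = 1.25,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standalone sparse linear system for coefficient-recovery benchmarks.

    X ~ N(0, 1) (samples x predictors); B0 has the given density with
    magnitudes uniform in [coef_low, coef_high] and random signs;
    Y = X @ B0 + Normal(0, noise_sd).  Returns (X, Y, B0).
    """
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_samples, n_predictors))
    mask = rng.random((n_predictors, n_responses)) < density
    B0 = np.where(
        mask,
        rng.uniform(coef_low, coef_high, size=mask.shape)
        * rng.choice([-1.0, 1.0], size=mask.shape),
        0.0,
    )
    Y = X @ B0 + rng.normal(0.0, noise_sd, size=(n_samples, n_responses))
    return X, Y, B0


def simulate_ppi(
    proteins: list[str], extra_density: float = 0.3, seed: int = 0
) -> tuple[PpiGraph, dict[str, set[str]]]:
    """Erdos-Renyi PPI fixture with its adjacency recorded as the oracle.

    Returns (graph, adjacency) where adjacency maps every protein to its
    neighbor set, so first-level expansion has an exact reference.
    Scores are uniform in [700, 1000] (the high-confidence band).
    """
    if len(proteins) < 2:
        raise ValueError("need at least 2 proteins")
    if not 0 <= extra_density <= 1:
        raise ValueError("extra_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    edges: dict[tuple[str, str], float] = {}
    adjacency: dict[str, set[str]] = {p: set() for p in proteins}
    for i, a in enumerate(proteins):
        for b in proteins[i + 1 :]:
            if rng.random() < extra_density:
                edges[tuple(sorted((a, b)))] = float(np.round(rng.uniform(700, 1000), 1))
                adjacency[a].add(b)
                adjacency[b].add(a)
    return PpiGraph(edges), adjacency
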