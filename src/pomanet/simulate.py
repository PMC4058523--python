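"""Synthetic paired miRNA/mRNA cohorts with known regulatory ground truth.

The generator emulates the data regime the pipeline is built for: a small
two-class cohort (6 controls vs 19 cases by default) of paired,
log-scale expression profiles in which

* planted regulator miRNAs carry a *subset-outlier* signal — a shift of
  ``planted_effect`` within-class SDs in only ``outlier_fraction`` of the
  case samples (the heterogeneous-tumor regime ordered-subset statistics
  target);
* each planted target gene tracks its regulator(s) inversely
  (``target = baseline − slope·regulator_deviation + noise``), giving a
  controlled generative anticorrelation; and
* the reference interaction network realizes an explicit exclusivity plan:
  some planted miRNAs own exclusive targets (in-degree 1), others share all
  their targets — exactly the structure the exclusivity Z-score discriminates.

Two regulator archetypes are planted by default: "exclusivity-rich" miRNAs
(6 exclusive targets each; coupling slope 2.0 → generative Spearman ≈ 0.894)
— the intended biomarkers — and "share-heavy" miRNAs arranged in correlated
pairs that co-own a pool of shared targets.  Co-owning regulators share a
latent factor (partner correlation 0.45) because two *independent* drivers
of one gene cannot both correlate strongly with it (ρ1² + ρ2² <= 1); with
shared slope 1.4 each shared edge reaches a generative |ρ| ≈ 0.785.
Co-owning regulators are additionally *co-deregulated*: the members of a
co-ownership group draw one outlier subset and one shift direction, the way
a coordinated miRNA program marks one tumor subtype.  Were the subsets
independent, the partner's subset shift would act as noise in the
(regulator, shared gene) correlation and push the realized |ρ| down to the
retention boundary; with co-deregulation the shifts reinforce it.

All randomness flows from one integer seed through a fixed draw order, so a
cohort is byte-reproducible.  Values are generated directly on the log2
scale (the pipeline consumes log-transformed processed values); matrices are
flagged ``log_scale=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import (
    ExpressionMatrix,
    InteractionEdgeList,
    SampleAnnotation,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegulatorPlan:
    """One planted miRNA: which targets it owns exclusively vs shares."""

    mirna_id: str
    exclusive_targets: tuple = ()
    shared_targets: tuple = ()

    @property
    def targets(self) -> tuple:
        return self.exclusive_targets + self.shared_targets


@dataclass
class GroundTruth:
    """Planted regulatory structure plus the effect-size conditions.

    ``shared_owners`` maps each shared gene to the two distinct regulators
    that co-own it; the exclusivity plan must be internally consistent
    (validated on construction) and is realized exactly in the generated
    reference network.
    """

    regulators: list = field(default_factory=list)  # list[RegulatorPlan]
    shared_owners: dict = field(default_factory=dict)  # gene -> (reg_a, reg_b)
    n_mirna: int = 100
    n_gene: int = 500
    planted_effect: float = 3.0  # shift in within-class SD units
    outlier_fraction: float = 0.6  # fraction of case samples carrying the shift
    slope: float = 2.0  # exclusive-target coupling
    shared_slope: float = 1.4  # shared-target coupling (per owner)
    partner_correlation: float = 0.45  # latent correlation of co-owners

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        by_id = {r.mirna_id: r for r in self.regulators}
        if len(by_id) != len(self.regulators):
            raise ValueError("duplicate regulator ids in ground truth")
        owners_of: dict = {}
        for r in self.regulators:
            for g in r.exclusive_targets:
                owners_of.setdefault(g, []).append((r.mirna_id, "exclusive"))
            for g in r.shared_targets:
                owners_of.setdefault(g, []).append((r.mirna_id, "shared"))
        for g, owners in owners_of.items():
            roles = {role for _, role in owners}
            if roles == {"exclusive"}:
                if len(owners) != 1:
                    raise ValueError(
                        f"infeasible exclusivity plan: gene {g!r} is exclusive "
                        f"to multiple regulators {[m for m, _ in owners]}"
                    )
                if g in self.shared_owners:
                    raise ValueError(
                        f"infeasible exclusivity plan: gene {g!r} is both "
                        "exclusive and shared"
                    )
            elif roles == {"shared"}:
                names = sorted(m for m, _ in owners)
                if len(names) != 2 or len(set(names)) != 2:
                    raise ValueError(
                        f"infeasible exclusivity plan: shared gene {g!r} must "
                        f"have exactly 2 distinct owners, got {names}"
                    )
                declared = tuple(sorted(self.shared_owners.get(g, ())))
                if declared != tuple(names):
                    raise ValueError(
                        f"shared gene {g!r}: owners {names} do not match "
                        f"shared_owners entry {declared}"
                    )
            else:
                raise ValueError(
                    f"infeasible exclusivity plan: gene {g!r} mixes exclusive "
                    "and shared roles"
                )
        n_partners = {}
        for a, b in self.correlated_pairs():
            n_partners[a] = n_partners.get(a, 0) + 1
            n_partners[b] = n_partners.get(b, 0) + 1
        for m, k in n_partners.items():
            if k * self.partner_correlation > 1.0:
                raise ValueError(
                    f"regulator {m!r} has {k} correlated partners; "
                    f"partner_correlation {self.partner_correlation} too large"
                )
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValueError("outlier_fraction must be in [0, 1]")

    # --- derived structure -------------------------------------------------
    def planted_mirnas(self) -> list:
        return [r.mirna_id for r in self.regulators]

    def planted_genes(self) -> list:
        seen: dict = {}
        for r in self.regulators:
            for g in r.targets:
                seen[g] = None
        return list(seen)

    def planted_edges(self) -> set:
        return {(r.mirna_id, g) for r in self.regulators for g in r.targets}

    def correlated_pairs(self) -> list:
        """Distinct regulator pairs that co-own at least one shared gene."""
        return sorted({tuple(sorted(v)) for v in self.shared_owners.values()})

    def expected_scores(self) -> pd.DataFrame:
        """(alpha, beta, Z) on the planted-only network, i.e. under perfect
        recovery of every planted edge."""
        rows = []
        for r in self.regulators:
            beta = len(r.targets)
            alpha = len(r.exclusive_targets)
            rows.append(
                {
                    "mirna_id": r.mirna_id,
                    "alpha": alpha,
                    "beta": beta,
                    "z": alpha / beta if beta else 0.0,
                }
            )
        return pd.DataFrame(rows, columns=["mirna_id", "alpha", "beta", "z"])

    def biomarker_mirnas(self, z_cutoff: float = 0.3, alpha_min: int = 1) -> list:
        """Regulators that satisfy the structural candidate thresholds under
        perfect recovery — the positives for sensitivity/precision scoring."""
        exp = self.expected_scores()
        keep = (exp["z"] >= z_cutoff - 1e-12) & (exp["alpha"] > alpha_min)
        return sorted(exp.loc[keep, "mirna_id"])

    def generative_rho(self) -> dict:
        """Analytic within-class Spearman-scale anticorrelation per planted
        edge (magnitude of the Pearson correlation of the generative model;
        rank correlation is marginally smaller)."""
        c = self.partner_correlation
        s_ex = self.slope
        s_sh = self.shared_slope
        rho_ex = s_ex / np.sqrt(s_ex ** 2 + 1.0)
        rho_sh = s_sh * (1 + c) / np.sqrt(2 * s_sh ** 2 * (1 + c) + 1.0)
        out = {}
        for r in self.regulators:
            for g in r.exclusive_targets:
                out[(r.mirna_id, g)] = float(rho_ex)
            for g in r.shared_targets:
                out[(r.mirna_id, g)] = float(rho_sh)
        return out


def mirna_name(i: int) -> str:
    return f"miR-{i + 1:03d}"


def gene_name(j: int) -> str:
    return f"GENE-{j + 1:04d}"


def default_truth(
    n_mirna: int = 100,
    n_gene: int = 500,
    n_rich: int = 4,
    exclusive_per_rich: int = 6,
    n_heavy_pairs: int = 3,
    shared_per_pair: int = 10,
    planted_effect: float = 3.0,
    outlier_fraction: float = 0.6,
    slope: float = 2.0,
    shared_slope: float = 1.4,
    partner_correlation: float = 0.45,
) -> GroundTruth:
    """Standard planted structure: ``n_rich`` exclusivity-rich regulators and
    ``n_heavy_pairs`` correlated share-heavy pairs (2 regulators each)."""
    n_planted_m = n_rich + 2 * n_heavy_pairs
    n_planted_g = n_rich * exclusive_per_rich + n_heavy_pairs * shared_per_pair
    if n_planted_m > n_mirna:
        raise ValueError("not enough miRNAs for the planted regulators")
    if n_planted_g > n_gene:
        raise ValueError("not enough genes for the planted targets")
    regulators = []
    shared_owners = {}
    gi = 0
    for i in range(n_rich):
        exc = tuple(gene_name(gi + t) for t in range(exclusive_per_rich))
        gi += exclusive_per_rich
        regulators.append(RegulatorPlan(mirna_name(i), exclusive_targets=exc))
    for p in range(n_heavy_pairs):
        a = mirna_name(n_rich + 2 * p)
        b = mirna_name(n_rich + 2 * p + 1)
        pool = tuple(gene_name(gi + t) for t in range(shared_per_pair))
        gi += shared_per_pair
        for g in pool:
            shared_owners[g] = (a, b)
        regulators.append(RegulatorPlan(a, shared_targets=pool))
        regulators.append(RegulatorPlan(b, shared_targets=pool))
    return GroundTruth(
        regulators=regulators,
        shared_owners=shared_owners,
        n_mirna=n_mirna,
        n_gene=n_gene,
        planted_effect=planted_effect,
        outlier_fraction=outlier_fraction,
        slope=slope,
        shared_slope=shared_slope,
        partner_correlation=partner_correlation,
    )


@dataclass
class Cohort:
    """A generated cohort plus the per-run realization of the truth."""

    mirna: ExpressionMatrix
    genes: ExpressionMatrix
    annotation: SampleAnnotation
    outlier_samples: dict  # regulator id -> tuple of shifted case sample ids
    directions: dict  # regulator id -> "up" | "down"


def generate_cohort(
    truth: GroundTruth,
    n_control: int = 6,
    n_case: int = 19,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline_loc: float = 8.0,
    baseline_scale: float = 2.0,
) -> Cohort:
    """Generate paired miRNA and mRNA matrices under the planted truth.

    Baseline expression is i.i.d. Normal(mu_f, noise_sd) on the log2 scale
    with per-feature means mu_f ~ Normal(baseline_loc, baseline_scale).
    Each planted regulator receives a ±planted_effect·noise_sd shift in a
    randomly chosen ``outlier_fraction`` of the case samples (sign random
    per regulator); targets follow their regulators inversely as described
    in the module docstring.  Decoy features are pure noise.
    """
    if n_control < 2 or n_case < 2:
        raise ValueError("need at least 2 samples per class")
    k_out = int(round(truth.outlier_fraction * n_case))
    if truth.regulators and k_out < 2:
        raise ValueError(
            f"outlier_fraction·n_case = {truth.outlier_fraction * n_case:.2f} "
            "< 2: LSOSS split undefined for the planted subset"
        )
    rng = np.random.default_rng(seed)
    n_samples = n_control + n_case
    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    classes = ["control"] * n_control + ["case"] * n_case
    ann = SampleAnnotation(
        pd.DataFrame(
            {"sample_id": sample_ids, "class_label": classes, "pair_key": sample_ids}
        )
    )
    case_cols = np.arange(n_control, n_samples)

    m_ids = [mirna_name(i) for i in range(truth.n_mirna)]
    g_ids = [gene_name(j) for j in range(truth.n_gene)]
    m_index = {m: i for i, m in enumerate(m_ids)}
    g_index = {g: j for j, g in enumerate(g_ids)}

    # fixed draw order for reproducibility (see module docstring)
    mirna_mu = rng.normal(baseline_loc, baseline_scale, truth.n_mirna)
    gene_mu = rng.normal(baseline_loc, baseline_scale, truth.n_gene)
    dev = rng.standard_normal((truth.n_mirna, n_samples))

    c = truth.partner_correlation
    pairs = truth.correlated_pairs()
    if pairs:
        latents = rng.standard_normal((len(pairs), n_samples))
        n_partners = np.zeros(truth.n_mirna)
        lat_sum = np.zeros((truth.n_mirna, n_samples))
        for p, (a, b) in enumerate(pairs):
            for m in (a, b):
                i = m_index[m]
                n_partners[i] += 1
                lat_sum[i] += latents[p]
        w = np.sqrt(np.maximum(1.0 - c * n_partners, 0.0))
        dev = w[:, None] * dev + np.sqrt(c) * lat_sum

    # co-owning regulators are co-deregulated: one outlier subset and one
    # shift direction per co-ownership group, so the shared-target
    # anticorrelation survives the subset shifts (see docs/methods.md)
    root: dict = {m: m for m in m_ids}

    def find(m):
        while root[m] != m:
            root[m] = root[root[m]]
            m = root[m]
        return m

    for a, b in pairs:
        root[find(a)] = find(b)

    group_draw: dict = {}
    outlier_samples: dict = {}
    directions: dict = {}
    for r in truth.regulators:
        key = find(r.mirna_id)
        if key not in group_draw:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            chosen = rng.choice(case_cols, size=k_out, replace=False)
            group_draw[key] = (direction, chosen)
        direction, chosen = group_draw[key]
        i = m_index[r.mirna_id]
        dev[i, chosen] += direction * truth.planted_effect
        outlier_samples[r.mirna_id] = tuple(
            sorted(sample_ids[int(cix)] for cix in chosen)
        )
        directions[r.mirna_id] = "up" if direction > 0 else "down"

    mirna_vals = mirna_mu[:, None] + noise_sd * dev

    gene_eps = rng.standard_normal((truth.n_gene, n_samples))
    gene_vals = gene_mu[:, None] + noise_sd * gene_eps
    for r in truth.regulators:
        i = m_index[r.mirna_id]
        for g in r.exclusive_targets:
            gene_vals[g_index[g]] -= truth.slope * noise_sd * dev[i]
        for g in r.shared_targets:
            gene_vals[g_index[g]] -= truth.shared_slope * noise_sd * dev[i]

    mirna_em = ExpressionMatrix(
        pd.DataFrame(mirna_vals, index=m_ids, columns=sample_ids),
        feature_kind="miRNA",
        log_scale=True,
    )
    gene_em = ExpressionMatrix(
        pd.DataFrame(gene_vals, index=g_ids, columns=sample_ids),
        feature_kind="mRNA",
        log_scale=True,
    )
    return Cohort(mirna_em, gene_em, ann, outlier_samples, directions)


def generate_reference_network(
    truth: GroundTruth, n_extra_edges: int = 500, seed: int = 0
) -> InteractionEdgeList:
    """Reference edge list: every planted edge plus random decoy edges.

    Decoy edges connect only decoy miRNAs to decoy genes, so the planted
    exclusivity plan (in-degree 1 for exclusive targets, 2 for shared) is
    realized exactly in the reference network as well.
    """
    m_ids = [mirna_name(i) for i in range(truth.n_mirna)]
    g_ids = [gene_name(j) for j in range(truth.n_gene)]
    planted_m = set(truth.planted_mirnas())
    planted_g = set(truth.planted_genes())
    decoy_m = [m for m in m_ids if m not in planted_m]
    decoy_g = [g for g in g_ids if g not in planted_g]
    universe = len(decoy_m) * len(decoy_g)
    if n_extra_edges > universe:
        raise ValueError(
            f"cannot place {n_extra_edges} decoy edges in a "
            f"{len(decoy_m)}×{len(decoy_g)} decoy universe"
        )
    edges = set(truth.planted_edges())
    provenance = {e: "planted" for e in edges}
    rng = np.random.default_rng(seed)
    flat = rng.choice(universe, size=n_extra_edges, replace=False)
    for f in flat:
        e = (decoy_m[f // len(decoy_g)], decoy_g[f % len(decoy_g)])
        edges.add(e)
        provenance[e] = "decoy"
    return InteractionEdgeList(edges, provenance)


def truth_table(truth: GroundTruth) -> pd.DataFrame:
    """Planted edges with role, regulator archetype and generative |rho|."""
    rho = truth.generative_rho()
    biomarkers = set(truth.biomarker_mirnas())
    rows = []
    for r in truth.regulators:
        cls = "exclusivity_rich" if r.mirna_id in biomarkers else "share_heavy"
        for g in r.exclusive_targets:
            rows.append((r.mirna_id, g, "exclusive", cls, rho[(r.mirna_id, g)]))
        for g in r.shared_targets:
            rows.append((r.mirna_id, g, "shared", cls, rho[(r.mirna_id, g)]))
    return pd.DataFrame(
        rows,
        columns=["mirna_id", "gene_id", "role", "regulator_class", "generative_rho"],
    )


def write_truth(truth: GroundTruth, path) -> None:
    truth_table(truth).to_csv(path, sep="\t", index=False)
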