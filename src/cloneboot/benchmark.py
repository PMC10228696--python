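"""Support-versus-accuracy benchmark on the built-in simulator.

Runs the complete bootstrap workflow over a batch of simulated
multi-tumor patients at desk scale — 5 tumor sites, 8–12 clones, 30–60
SNVs, mean sequencing depth 100, 30 bootstrap replicates per dataset,
alternating monoclonal and polyclonal seeding — and aggregates the
support-accuracy statistics: genotype error of consensus clones by
bootstrap-support bin, the proportion of low-support consensus clones,
and the bootstrap supports of true-positive and false-positive migration
paths.

Consensus-clone GE uses pairwise-deletion scoring (ambiguous sites are
excluded from the comparison, as sequence-distance software treats an N);
the half-mismatch scoring is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import RunConfig
from .evaluate import nearest_true_ge
from .migration import path_supports
from .pipeline import run_pipeline
from .simulate import simulate_reads, simulate_truth

logger = logging.getLogger("cloneboot")


@dataclass
class BenchmarkResult:
    n_datasets: int
    support: dict[str, float] = field(default_factory=dict)      # clone key -> %
    ge_ignore: dict[str, float] = field(default_factory=dict)    # pairwise deletion
    ge_half: dict[str, float] = field(default_factory=dict)      # 0.5 per ambiguity
    tp_supports: list[float] = field(default_factory=list)
    fp_supports: list[float] = field(default_factory=list)

    def high_support_ges(self, cutoff: float = 50.0,
                         scoring: str = "ignore") -> list[float]:
        ge = self.ge_ignore if scoring == "ignore" else self.ge_half
        return [ge[k] for k, s in self.support.items() if s > cutoff]

    def low_support_fraction(self, cutoff: float = 10.0) -> float:
        return float(np.mean([s <= cutoff for s in self.support.values()]))

    def summary(self) -> dict:
        hi_i = self.high_support_ges(scoring="ignore")
        hi_h = self.high_support_ges(scoring="half")
        out = {
            "n_datasets": self.n_datasets,
            "n_consensus_clones": len(self.support),
            "n_high_support_clones": len(hi_i),
            "median_ge_high_support": float(np.median(hi_i)) if hi_i else float("nan"),
            "median_ge_high_support_half": float(np.median(hi_h)) if hi_h else float("nan"),
            "low_support_clone_percent": 100.0 * self.low_support_fraction(),
            "n_tp_paths": len(self.tp_supports),
            "n_fp_paths": len(self.fp_supports),
        }
        if self.tp_supports:
            out["tp_path_support_median"] = float(np.median(self.tp_supports))
        if self.fp_supports:
            out["fp_path_support_median"] = float(np.median(self.fp_supports))
        return out


def dataset_conditions(n_datasets: int) -> list[dict]:
    """The simulated study conditions: one dict per dataset."""
    # 9..12 clones (polyclonal seeding of 4 metastases needs >= 9), 30..60
    # SNVs, 5 tumor sites, alternating seeding modes
    return [{
        "n_clones": 9 + (i % 4),
        "n_snvs": 30 + (3 * i) % 31,
        "n_samples": 5,
        "seeding_mode": "monoclonal" if i % 2 else "polyclonal",
    } for i in range(n_datasets)]


def support_accuracy_benchmark(seed: int, n_datasets: int = 10,
                               n_replicates: int = 30,
                               depth_mean: float = 100.0) -> BenchmarkResult:
    """Run the benchmark; all randomness derives from ``seed``."""
    streams = np.random.SeedSequence(seed).spawn(n_datasets)
    result = BenchmarkResult(n_datasets=n_datasets)
    for i, (cond, ss) in enumerate(zip(dataset_conditions(n_datasets), streams)):
        s_truth, s_reads, s_boot = (int(x % (2**31))
                                    for x in ss.generate_state(3))
        truth = simulate_truth(seed=s_truth, **cond)
        counts = simulate_reads(truth, seed=s_reads, depth_mean=depth_mean)
        cfg = RunConfig(n_replicates=n_replicates, rng_seed=s_boot)
        res = run_pipeline(counts, cfg, primary=truth.primary)

        gei = nearest_true_ge(res.consensus_genotypes, truth.genotypes,
                              ambiguity="ignore")
        geh = nearest_true_ge(res.consensus_genotypes, truth.genotypes,
                              ambiguity="half")
        for cid, s in res.consensus_support.items():
            key = f"d{i}:{cid}"
            result.support[key] = s
            result.ge_ignore[key] = gei[cid]
            result.ge_half[key] = geh[cid]

        true_paths = truth.history.path_set()
        for path, s in path_supports(res.replicate_histories).items():
            (result.tp_supports if path in true_paths
             else result.fp_supports).append(s)
        logger.info("benchmark dataset %d/%d done", i + 1, n_datasets)
    return result
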