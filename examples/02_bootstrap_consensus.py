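"""Bootstrap support for inferred clones.

Resamples sequencing reads to make 30 pseudo-multi-tumor replicate
datasets, infers clones in each, groups near-identical bootstrap clones
and prints the consensus genotypes with their bootstrap supports.
"""

from cloneboot import (AMBIGUOUS, RunConfig, run_pipeline, simulate_reads,
                       simulate_truth)

truth = simulate_truth(n_clones=8, n_snvs=30, n_samples=5,
                       seeding_mode="monoclonal", seed=11)
counts = simulate_reads(truth, seed=12, depth_mean=100)

result = run_pipeline(counts, RunConfig(n_replicates=30, rng_seed=5))

print(f"{result.consensus_genotypes.n_clones} consensus clones "
      f"from 30 bootstrap replicates\n")
print("clone  support%  genotype (?=ambiguous)")
for cid in result.consensus_genotypes.clone_ids[:10]:
    row = result.consensus_genotypes.row(cid)
    seq = "".join("?" if x == AMBIGUOUS else str(x) for x in row)
    print(f"{cid:>5}  {result.consensus_support[cid]:7.1f}  {seq}")

# A clone's support is the percentage of bootstrap replicates in which a
# (nearly) identical genotype was inferred; a base is called in the
# consensus only when >90% of the group's members agree, otherwise it is
# reported as ambiguous. High-support clones are reliable; the long tail
# of low-support clones is where inference uncertainty concentrates.
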