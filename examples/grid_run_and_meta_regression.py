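"""Run a slice of the simulation grid and summarize it by regression.

Takes the all-1%-MAF risk-increasing settings across the eps01-only error
levels, estimates empirical power of the J2 statistic by phenotype
permutation (reduced replicate counts keep this quick), and regresses
power on the coded design factors.  The error-magnitude coefficient is
negative — each step up the 0/1/5 error scale costs several points of
power — matching the direction of the full-scale study.
"""
from genoerr import RunConfig, nondifferential_grid, run_grid, summarize_grid

labels = [s.label for s in nondifferential_grid()
          if not s.is_null and s.errors.eps10_control[0] == 0.0
          and "mix=all_risk_increasing|" in s.label]

config = RunConfig(grid="non_differential", n_reps=80, n_permutations=150,
                   seed=1, statistics=[("joint", 2)], labels=labels)
table = run_grid(config)
print(table[["label", "rate", "mc_se"]].to_string(index=False))

model = summarize_grid(table, response="power")
print()
print(model)
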