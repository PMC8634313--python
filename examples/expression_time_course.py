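"""Quantify TE family expression and call differential expression.

Simulates a joint gene + TE count table with planted fold changes
(mock vs infected, three replicates each). Genes carry most of the
library, as in a real transcriptome, so TE families sit at realistic
TPM levels; they are used for normalization and then dropped from the
differential-expression report. The NB Wald engine applies the
padj < 0.05 and |log2FC| >= 2 rule, and families crossing the 4-TPM
expression threshold are classified induced or repressed.
"""

import numpy as np
import pandas as pd

from tevex import expression as ex
from tevex import sim

rng = np.random.default_rng(11)

# 2000 genes dominate the library; 200 TE families are mostly silent or
# lowly expressed, with a few planted effects: strong up/down shifts,
# one family switching on from silence and one switching off
truth = [sim.CountSimTruth(f"gene_{i}", 0.0, float(rng.uniform(50, 2000)), 0.05)
         for i in range(2000)]
truth += [sim.CountSimTruth(f"te_{i}", 0.0, float(rng.exponential(2.0)) + 0.05, 0.05)
          for i in range(195)]
truth += [
    sim.CountSimTruth("te_up_strong", 5.0, 30.0, 0.05),
    sim.CountSimTruth("te_up_mild", 3.0, 60.0, 0.05),
    sim.CountSimTruth("te_down", -4.0, 90.0, 0.05),
    sim.CountSimTruth("te_induced", 6.0, 1.0, 0.05),     # silent in mock
    sim.CountSimTruth("te_repressed", -6.0, 40.0, 0.05),
]
counts, samples = sim.simulate_count_table(truth, 3, seed=11)
samples["time_point"] = 48
meta = pd.DataFrame(
    {"kind": ["gene"] * 2000 + ["te_family"] * 200, "length": 1000},
    index=counts.index,
)
table = ex.CountTable(counts=counts, meta=meta, samples=samples)

tpm = ex.compute_tpm(table)
te_tpm = tpm.loc[table.te_names]
print(f"TPM columns each sum to {tpm.sum(axis=0).iloc[0]:,.0f} (by construction)")
mock_tpm = te_tpm.loc[:, samples.condition == "mock"].mean(axis=1)
print(f"median mock TE TPM: {mock_tpm.median():.2f}; "
      f"{(mock_tpm < 4).sum()}/{len(mock_tpm)} TE families below the 4-TPM "
      f"expression cutoff in the mock")
categories = ex.classify_expression_series(mock_tpm).value_counts()
print("mock expression categories:", categories.to_dict())

res = ex.call_de(table, design="matched")  # genes normalized, TEs reported
de = res[res.de_flag != "ns"].set_index("entity")
print(f"differentially expressed TE families (padj<0.05, |log2FC|>=2): {len(de)}")
print(de[["log2fc", "padj", "de_flag"]].round(3).to_string())

flags = res.pivot_table(index="entity", columns="time_point", values="de_flag",
                        aggfunc="first")
inf_tpm = te_tpm.loc[:, samples.condition == "infected"].mean(axis=1).to_frame(48)
status = ex.classify_induced_repressed(flags, mock_tpm.to_frame("mock"), inf_tpm)
print("induced (silent in mock, expressed and upregulated when infected):",
      list(status.index[status.induced]))
print("repressed (expressed in mock, silenced when infected):",
      list(status.index[status.repressed]))

# correlation of expression with family covariates: copy number is the
# planted driver here, age (divergence) is independent noise
factors = pd.DataFrame(
    {
        "copy_number": (mock_tpm * rng.uniform(0.8, 1.2, len(mock_tpm))).round() + 1,
        "mean_divergence": rng.uniform(0, 30, len(mock_tpm)),
    },
    index=mock_tpm.index,
)
corr = ex.correlate_factors(mock_tpm, factors)
print("Pearson correlation of mock TE expression with family factors:")
print(corr.round(3).to_string())
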