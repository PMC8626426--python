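"""Validate the precursor model with two-lysine (missed-cleavage) peptides.

Peptides with one missed Lys-C cleavage carry two lysines and hence three
label combinations (Lys0Lys0, Lys0Lys8, Lys8Lys8). These peptides never
train the tissue coefficients, so comparing their observed three-way
fractions with the model's predictions is an independent check of the
precursor model.
"""

import tempfile
from pathlib import Path

from turnoverkit import (
    SimulationSpec,
    read_quantified_peptides,
    run_pipeline,
    validate_missed_cleavage,
)
from turnoverkit.simulate import simulate_tissue

spec = SimulationSpec(n_proteins=80, seed=21, fraction_missed_cleavage=0.15)
sim = simulate_tissue(spec)
with tempfile.TemporaryDirectory() as tmp:
    table = Path(tmp) / "t.tsv"
    sim.table.to_csv(table, sep="\t", index=False)
    series = read_quantified_peptides(table)
run = run_pipeline(series, database=sim.fasta, tissue="demo", seed=3,
                   n_sims=30)

table, r2 = validate_missed_cleavage(run)
n_pep = table["full_sequence"].nunique() if not table.empty else 0
print(f"{n_pep} missed-cleavage peptides, {len(table)} fraction observations")
print(f"pooled R^2 (observed vs expected fractions): {r2:.4f}")
print("\nfirst observations (one row per label channel):")
print(table.head(9).to_string(index=False,
                              float_format=lambda v: f"{v:.4f}"))
print("\nAn R^2 near 1 means the fitted recycling-corrected precursor")
print("curve predicts the two-lysine isotopologue mix it never saw in")
print("training — the model's internal consistency check.")
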