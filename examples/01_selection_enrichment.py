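"""Selection-round enrichment: simulate six rounds and profile k-mers.

Generates a random 30-nt insert library, runs six rounds of affinity
selection under an A/C-favouring ground-truth model, and prints the
monomer composition of the top-ranked sequences per round.  The rising
A+C share mirrors the enrichment a real selection experiment shows.
"""

from cntbind import library, synthetic

model = synthetic.ac_favoring_model(strength=0.1, temperature=1.0)
rounds = synthetic.simulate_selection(
    model, n_unique=20000, n_rounds=6, n_draw=30000, pcr_cv=0.2, seed=1
)

table = library.enrichment_table(rounds, k=1, n_top=20000)
print("monomer composition of the top-ranked sequences per round (%):")
print((100 * table.table).round(1).to_string())
print()
for r in (0, 6):
    print(f"round {r}: A+C = {100 * table.frequency(r, 'AC'):.1f}%")
print()
print(
    "A and C gain share every round while G and T decline - the signature\n"
    "of selection for the base pattern the affinity model favours."
)
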