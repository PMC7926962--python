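"""Low-PMF conformational-state extraction and binder classification.

Loads the packaged worked-example state tables of an engineered
pH-switchable anti-TNF-alpha antibody (BRRMSD, D3, PMF at pH 6.0 and 7.4),
applies the 50 kcal/mol PMF filter and classifies states by BRRMSD: at or
below 1.5 A the paratope geometry is binder-like, at or above 2.5 A it is
not.
"""

from phmd.structure import classify_states, filter_states, load_example_state_table

for ph in (6.0, 7.4):
    table = load_example_state_table(ph)
    low = filter_states(table, pmf_cutoff=50.0)
    counts = classify_states(low, bind_max=1.5, nonbind_min=2.5)
    print(f"pH {ph}: {len(low)} states under 50 kcal/mol -> "
          f"{counts.binder_like} binder-like, {counts.non_binder_like} non-binder-like, "
          f"{counts.indeterminate} indeterminate")

# First low-PMF area at pH 7.4 (BRRMSD 1.0-1.5 A, D3 11-13 A): the states
# predicted to retain TNF-alpha binding at cytoplasmic pH.
area = filter_states(load_example_state_table(7.4), pmf_cutoff=50.0,
                     brrmsd_range=(1.0, 1.5), d3_range=(11.0, 13.0))
print(f"\npH 7.4 first area (binder-like basin): {len(area)} states")
print(area.to_string(index=False))
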