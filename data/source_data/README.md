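# Deposited source-data tables (not included)

The acceptance check `test_anova_f_reproduction_from_deposited_tables`
re-computes one-way ANOVA F statistics from the original study's deposited
per-cell measurement tables. Those tables are distributed as supplementary
files with the publication and are not redistributed here.

To run the check, export each deposited table to CSV with the columns

    value, cell_id, animal_id, group_label

(one row per cell; `value` is the synapse density) and place them in this
directory as:

- `gain_of_function_inhibitory.csv` — perisomatic GAD65+/CB1R+ bouton
  densities for the three electroporation groups (expected F = 11.100)
- `gain_of_function_excitatory.csv` — VGlut1+/PSD95+ synapse densities on
  PV+ interneurons for the same groups (expected F = 22.120)
- `ct_swap_excitatory.csv` — the C-terminal-domain swap excitatory-synapse
  experiment (expected F = 0.679)

The test averages cells per animal with `synquant.animal_means` and runs
`synquant.oneway_anova_f` on the per-animal means.
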