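#!/bin/sh
# Run the five pipeline stages from the shell on a small synthetic cohort.
# Each stage persists tab-separated tables plus a JSON run log, and can be
# re-run in isolation from those intermediates.
set -e

cat > /tmp/omixwas_demo.yaml <<'YAML'
sim:
  n_train_samples: 300
  n_genes: 12
  n_variants_per_gene: 10
  n_mediated_genes: 6
  mediated_var_frac: 0.01
  n_gwas_samples: 4000
  n_tissues: 2
n_pcs: 5
n_surrogates: 5
trait_names: [LDL]
YAML

omixwas all --config /tmp/omixwas_demo.yaml --seed 5 --out-dir /tmp/omixwas_run
echo "--- association table head ---"
head -5 /tmp/omixwas_run/associations.tsv
echo "--- concordance ---"
cat /tmp/omixwas_run/concordance.tsv
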