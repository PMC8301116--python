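# Default per-property model settings: pretreatment, latent-variable
# count and spectral ranges (ppm, [high, low] pairs).  Reducing sugars
# are modeled on the 55-220 ppm range, excluding the lipid-dominated
# aliphatic region; other properties use the full spectrum unless a
# range study suggests otherwise.
split:
  method: pca_coverage
  n_val: 10
  n_boot: 200
  k_pcs: 5
  seed: 0
properties:
  reducing_sugars: {pretreatment: msc, n_lv: 4, ranges: [[220, 55]]}
  protein: {pretreatment: snv, n_lv: 4}
  fat: {pretreatment: snv, n_lv: 4}
  nhcs: {pretreatment: none, n_lv: 5}
  c: {pretreatment: none, n_lv: 5}
  n: {pretreatment: snv, n_lv: 4}
  s: {pretreatment: msc, n_lv: 5}
  tp: {pretreatment: msc, n_lv: 4}
  abts: {pretreatment: none, n_lv: 3}
  ph: {pretreatment: none, n_lv: 7}
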