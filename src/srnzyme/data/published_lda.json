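{
 "type": "lda",
 "coefficients": {
  "Tr3_mean": -0.95,
  "Tr5_mean": -0.8,
  "DTr5": -0.8,
  "DTr3": 1.01
 },
 "intercept": -2.05,
 "metadata": {
  "feature_names": ["Tr3_mean", "Tr5_mean", "DTr3", "DTr5"],
  "source": "published linear discriminant shipped as the package default"
 }
}
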