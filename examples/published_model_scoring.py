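"""Score pair features with the published linear discriminant.

The score is
    -0.95*<Tr3> - 0.80*<Tr5> - 0.80*DTr5 + 1.01*DTr3 - 2.05,
where <.> are candidate-class means and D terms are the sequence's
deviations from them.  A positive score calls the (sequence, class) pair an
enzyme of that class.
"""

from srnzyme import classify, load_default_model

model = load_default_model()
print("coefficients:", model.coefficients, "intercept:", model.intercept)

examples = [
    ("zero features (intercept only)", {"Tr3_mean": 0, "Tr5_mean": 0, "DTr3": 0, "DTr5": 0}),
    ("unit class means", {"Tr3_mean": 1, "Tr5_mean": 1, "DTr3": 0, "DTr5": 0}),
    ("unit DTr3", {"Tr3_mean": 0, "Tr5_mean": 0, "DTr3": 1, "DTr5": 0}),
    ("strong positive deviation", {"Tr3_mean": 0.5, "Tr5_mean": 0.5, "DTr3": 4.0, "DTr5": 0.2}),
]
for name, feats in examples:
    s = model.score(feats)
    print(f"  {name:32s} score {s:+.2f} -> label {classify(s):+d}")
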