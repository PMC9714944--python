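"""Ambiguity and misclassification rates from a normal error model.

A measured copy number at true count n is n(1+X) with relative error
X ~ N(mu, sigma^2).  The +-0.3 calling windows shrink as 1/n on the
relative-error axis, so ambiguity and misclassification grow with n.
The example also inverts the mapping: given two ambiguity rates of a
published table, it recovers (|mu|, sigma) and predicts the rest of the
column.
"""

from qgcn import ErrorModel, fit_error_model, format_rate_table, rate_at_gcn, rate_table

model = ErrorModel(mu=0.0, sigma=0.05)
table = rate_table({"5%-CV assay": model})
print("rates for an unbiased assay with 5% relative-error SD:")
print(format_rate_table(table).to_string())

# invert two published ambiguity cells (copy numbers 2 and 3) ...
fitted = fit_error_model([(2, 6.16), (3, 21.27)])
print(f"\nfitted from ambiguity 6.16% @2 and 21.27% @3: "
      f"|mu|={fitted.mu:.4f}, sigma={fitted.sigma:.4f}")
# ... and predict the remaining cells of the same column
for n in (1, 2, 3, 4):
    amb, mis = rate_at_gcn(fitted, n)
    print(f"  n={n}: ambiguity {amb:6.2f}%   misclassification {mis:5.2f}%")
print("A single-copy call is essentially never ambiguous, while at 4 "
      "copies roughly a third of measurements fall between integers.")
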