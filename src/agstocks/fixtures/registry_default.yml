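# Default allometric-model registry.
# Replace the generic entries with locally fitted equations; the schema is
#   model_id, form (power_product | power_dbh | linear_combination),
#   coefficients {a, b[, c]}, applies_to {species: [...], lulc: [...]},
#   dbh_range [min_cm, max_cm] (optional).
# Routing: species-specific > LULC-specific > default (the entry with no
# applies_to scope).
- model_id: pantropical-default
  form: power_product           # B = a * (rho * D^2 * H)^b, kg dry matter
  coefficients: {a: 0.0673, b: 0.976}
- model_id: palm-coconut
  form: linear_combination      # palms do not follow D^2*H scaling
  coefficients: {a: -6.0, b: 8.0, c: 0.1}
  applies_to:
    species: [Phoenix reclinata, Borassus flabellifer]
  dbh_range: [10.0, 60.0]
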