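{
  "tpi": {
    "full_name": "rabbit muscle triosephosphate isomerase (EC 5.3.1.1)",
    "n_states": 4,
    "scheme_variant": "standard",
    "second_order": {"k1": 1e7, "k8": 4e8},
    "first_order": {"k2": 7000.0, "k3": 2000.0, "k4": 6000.0, "k5": 60000.0, "k6": 90000.0, "k7": 4000.0},
    "environment": {"substrate_conc": 4e-5, "product_conc": 6.4e-8, "enzyme_conc": 5e-8, "temperature_label": "about 20 C"}
  },
  "ksi": {
    "full_name": "Comamonas testosteroni ketosteroid isomerase (EC 5.3.3.1)",
    "n_states": 4,
    "scheme_variant": "standard",
    "second_order": {"k1": 8.3e8, "k8": 1e9},
    "first_order": {"k2": 8.6e4, "k3": 1.8e5, "k4": 1.7e6, "k5": 6.4e5, "k6": 43.0, "k7": 1.5e5},
    "environment": {"substrate_conc": 1e-4, "product_conc": 5e-5, "enzyme_conc": 5e-6, "temperature_label": "25 C"},
    "alt_columns": {
      "direct_measurement": {
        "comment": "earlier directly measured set; k4 and k5 are lower bounds as published",
        "second_order": {"k1": 8.6e8, "k8": 8.6e8},
        "first_order": {"k2": 8.6e4, "k3": 1.7e5, "k4": 3e5, "k5": 1e5, "k6": 40.0, "k7": 1.3e5}
      }
    }
  },
  "ca1": {
    "full_name": "human carbonic anhydrase I (EC 4.2.1.1), buffer-assisted scheme",
    "n_states": 4,
    "scheme_variant": "ca_buffer",
    "second_order": {"k1": 3.4e7, "k4": 2.6e7, "k7": 1.1e8, "k8": 9.0e5},
    "first_order": {"k2": 3.8e4, "k3": 2.9e5, "k5": 9.0e5, "k6": 9.0e6},
    "environment": {"substrate_conc": 1.2e-3, "product_conc": 2.4e-2, "buffer_conc": 5.0e-2, "enzyme_conc": 1.0e-4, "temperature_label": "25 C"}
  },
  "ca2": {
    "full_name": "human carbonic anhydrase II (EC 4.2.1.1), buffer-assisted scheme",
    "n_states": 4,
    "scheme_variant": "ca_buffer",
    "second_order": {"k1": 1.3e8, "k4": 2.0e8, "k7": 4.0e8, "k8": 2.0e7},
    "first_order": {"k2": 1.8e6, "k3": 1.7e7, "k5": 1.2e6, "k6": 1.2e6},
    "environment": {"substrate_conc": 1.2e-3, "product_conc": 2.4e-2, "buffer_conc": 5.0e-2, "enzyme_conc": 1.0e-4, "temperature_label": "25 C"}
  },
  "ca2_t200h": {
    "full_name": "human carbonic anhydrase II T200H mutant, buffer-assisted scheme",
    "n_states": 4,
    "scheme_variant": "ca_buffer",
    "second_order": {"k1": 8.2e7, "k4": 9.0e6, "k7": 3.6e8, "k8": 1.8e7},
    "first_order": {"k2": 5.4e4, "k3": 3.0e5, "k5": 2.7e6, "k6": 2.1e7},
    "environment": {"substrate_conc": 1.2e-3, "product_conc": 2.4e-2, "buffer_conc": 5.0e-2, "enzyme_conc": 1.0e-4, "temperature_label": "25 C"}
  },
  "pc1": {
    "full_name": "Staphylococcus aureus PC1 beta-lactamase (EC 3.5.2.6)",
    "n_states": 3,
    "scheme_variant": "standard",
    "second_order": {"k1": 2.2e7, "k6": 1.0e6},
    "first_order": {"k2": 196.0, "k3": 173.0, "k4": 4.0, "k5": 96.0},
    "environment": {"substrate_conc": 1.492e-3, "product_conc": 8.0e-6, "enzyme_conc": 1e-5, "temperature_label": "20 C"}
  },
  "rtem": {
    "full_name": "Escherichia coli RTEM beta-lactamase (EC 3.5.2.6)",
    "n_states": 3,
    "scheme_variant": "standard",
    "second_order": {"k1": 1.23e8, "k6": 4.0e7},
    "first_order": {"k2": 1.18e4, "k3": 2.8e3, "k4": 6.0, "k5": 1.5e3},
    "environment": {"substrate_conc": 1.390e-3, "product_conc": 1.1e-4, "enzyme_conc": 1e-5, "temperature_label": "20 C"}
  },
  "lac1": {
    "full_name": "Bacillus cereus Lac-1 beta-lactamase (EC 3.5.2.6)",
    "n_states": 3,
    "scheme_variant": "standard",
    "second_order": {"k1": 4.1e7, "k6": 8.0e6},
    "first_order": {"k2": 2.32e3, "k3": 4.09e3, "k4": 50.0, "k5": 3.61e3},
    "environment": {"substrate_conc": 1.285e-3, "product_conc": 2.15e-4, "enzyme_conc": 1e-5, "temperature_label": "20 C"}
  },
  "beta_gal": {
    "full_name": "Escherichia coli beta-galactosidase (EC 3.2.1.23)",
    "n_states": 2,
    "scheme_variant": "standard",
    "second_order": {"k1": 5.0e7, "k4": 1.0e2},
    "first_order": {"k2": 1.83e4, "k3": 7.3e2},
    "environment": {"substrate_conc": 1e-4, "product_conc": 1e-7, "enzyme_conc": 1e-6, "temperature_label": "25 C"},
    "comment": "k4 second-order value back-derived from the published pseudo-first-order k4 = 1e-5 s^-1 at [P] = 1e-7 M, which is the value every published derived quantity (Keq, X_tot/RT, P) is consistent with"
  },
  "glucose_isomerase": {
    "full_name": "Streptomyces murinus glucose (xylose) isomerase (EC 5.3.1.5)",
    "n_states": 2,
    "scheme_variant": "standard",
    "second_order": {"k1": 0.063, "k4": 0.082},
    "first_order": {"k2": 0.021, "k3": 0.029},
    "environment": {"substrate_conc": 2.0, "product_conc": 0.2, "enzyme_conc": 0.01, "temperature_label": "65 C"}
  }
}
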