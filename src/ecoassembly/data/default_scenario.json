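{
  "version": 1,
  "n_taxa": 80,
  "n_sites": 12,
  "total_per_site": 1000,
  "birth_rate": 1.0,
  "trait_sigma": 1.0,
  "niche_width": 0.3,
  "dispersal_scale": 0.1,
  "mixing": 0.8,
  "capacity_sigma": 1.0,
  "site_noise_sigma": 1.0
}
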