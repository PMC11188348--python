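# Cleanest city archetype (target composite air-quality index 2.3).
# sum(mean_p / S_p) = 0.7 + 0.5 + 0.6 + 0.5 = 2.3.
name: city_K
target_composite_index: 2.3
pollutants:
  pm25: {mean: 24.5}
  no2: {mean: 20.0}
  pm10: {mean: 42.0}
  o3: {mean: 80.0}
pollutant_cv: 0.30
pm25_pm10_rho: 0.80
water:
  heavy_metal: {mean: 0.020, cv: 0.15}
  dissolved_oxygen: {mean: 7.5, sd: 0.8}
  ph: {mean: 7.5, sd: 0.3}
soil:
  organic_matter: {mean: 3.0, cv: 0.15}
  n_p_content: {mean: 600.0, cv: 0.15}
noise: {mean: 55.0, sd: 6.0}
thermal:
  temperature: {mean: 22.0, sd: 3.0}
  wind_speed: {mean: 2.2, sd: 0.9}
  relative_humidity: {mean: 68.0, sd: 8.0}
# cleaner air: noise is the stronger latent driver
latent: {pm25_weight: 0.45, noise_weight: 0.55, noise_sd: 0.25}
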