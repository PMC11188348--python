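# Most-polluted city archetype (target composite air-quality index 3.92).
# Pollutant means satisfy sum(mean_p / S_p) = 3.92 against the default
# secondary standards (35 / 40 / 70 / 160): 1.4 + 0.9 + 1.0 + 0.62.
name: city_B
target_composite_index: 3.92
pollutants:
  pm25: {mean: 49.0}
  no2: {mean: 36.0}
  pm10: {mean: 70.0}
  o3: {mean: 99.2}
pollutant_cv: 0.30
pm25_pm10_rho: 0.80
water:
  heavy_metal: {mean: 0.040, cv: 0.15}
  dissolved_oxygen: {mean: 6.0, sd: 0.8}
  ph: {mean: 7.5, sd: 0.3}
soil:
  organic_matter: {mean: 4.0, cv: 0.15}
  n_p_content: {mean: 800.0, cv: 0.15}
noise: {mean: 62.0, sd: 6.0}
thermal:
  temperature: {mean: 27.0, sd: 4.0}
  wind_speed: {mean: 2.5, sd: 1.0}
  relative_humidity: {mean: 55.0, sd: 10.0}
# latent risk loads on PM2.5 above noise (heavy-particulate-driven city)
latent: {pm25_weight: 0.8, noise_weight: 0.5, noise_sd: 0.25}
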