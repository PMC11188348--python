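# Moderately-polluted city archetype (target composite air-quality index 3.04).
# sum(mean_p / S_p) = 1.0 + 0.7 + 0.8 + 0.54 = 3.04.
name: city_W
target_composite_index: 3.04
pollutants:
  pm25: {mean: 35.0}
  no2: {mean: 28.0}
  pm10: {mean: 56.0}
  o3: {mean: 86.4}
pollutant_cv: 0.30
pm25_pm10_rho: 0.80
water:
  heavy_metal: {mean: 0.030, cv: 0.15}
  dissolved_oxygen: {mean: 6.5, sd: 0.8}
  ph: {mean: 7.5, sd: 0.3}
soil:
  organic_matter: {mean: 3.5, cv: 0.15}
  n_p_content: {mean: 700.0, cv: 0.15}
noise: {mean: 60.0, sd: 6.0}
thermal:
  temperature: {mean: 26.0, sd: 4.0}
  wind_speed: {mean: 2.8, sd: 1.0}
  relative_humidity: {mean: 65.0, sd: 10.0}
# latent risk loads on noise above PM2.5 (noise-driven moderate city)
latent: {pm25_weight: 0.62, noise_weight: 0.7, noise_sd: 0.25}
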