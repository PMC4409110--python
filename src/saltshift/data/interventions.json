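{
  "counselling": {
    "label": "Dietary counselling",
    "mandatory": false,
    "schedule": "immediate",
    "phase_years": 1,
    "effect_mean_mmol": null,
    "effect_sd_fraction": null,
    "effect_distribution": "normal",
    "effect_components": {
      "per_hour_effect_mmol": 7.6,
      "per_hour_sd_mmol": 0.8,
      "annual_hours": 4600,
      "annual_hours_sd": 920,
      "adult_population": 2300000
    },
    "cost_nzd": 575000,
    "cost_recurring": true,
    "cost_sd_fraction": 0.10,
    "cost_distribution": "gamma"
  },
  "endorsement_label": {
    "label": "Endorsement Label Programme",
    "mandatory": false,
    "schedule": "immediate",
    "phase_years": 1,
    "effect_mean_mmol": 1.7,
    "effect_sd_fraction": 0.20,
    "effect_distribution": "normal",
    "cost_nzd": 621000,
    "cost_recurring": true,
    "cost_sd_fraction": 0.10,
    "cost_distribution": "gamma"
  },
  "mandatory_3g": {
    "label": "Mandatory 25% sodium reduction: bread, processed meats, sauces",
    "mandatory": true,
    "schedule": "immediate",
    "phase_years": 1,
    "effect_mean_mmol": 12.9,
    "effect_sd_fraction": 0.10,
    "effect_distribution": "normal",
    "cost_nzd": 3680000,
    "cost_recurring": false,
    "cost_sd_fraction": 0.25,
    "cost_distribution": "gamma"
  },
  "mandatory_all": {
    "label": "Mandatory 25% sodium reduction: all processed foods",
    "mandatory": true,
    "schedule": "immediate",
    "phase_years": 1,
    "effect_mean_mmol": 22.8,
    "effect_sd_fraction": 0.10,
    "effect_distribution": "normal",
    "cost_nzd": 3680000,
    "cost_recurring": false,
    "cost_sd_fraction": 0.25,
    "cost_distribution": "gamma"
  },
  "uk_package": {
    "label": "UK package (media campaign + reformulation + labelling)",
    "mandatory": false,
    "schedule": "linear",
    "phase_years": 7,
    "effect_mean_mmol": 22.7,
    "effect_sd_fraction": 0.10,
    "effect_distribution": "normal",
    "cost_nzd": 12100000,
    "cost_recurring": false,
    "cost_sd_fraction": 0.10,
    "cost_distribution": "gamma"
  },
  "uk_media": {
    "label": "UK mass media campaign alone",
    "mandatory": false,
    "schedule": "linear",
    "phase_years": 7,
    "effect_mean_mmol": null,
    "effect_sd_fraction": 0.30,
    "effect_distribution": "normal",
    "effect_components": {
      "campaign_share": 0.30,
      "package_total_mmol": 22.7
    },
    "cost_nzd": 10400000,
    "cost_recurring": false,
    "cost_sd_fraction": 0.10,
    "cost_distribution": "gamma"
  },
  "salt_tax": {
    "label": "Salt excise tax to a 2300 mg/d intake target",
    "mandatory": true,
    "schedule": "tax",
    "phase_years": 10,
    "effect_mean_mmol": null,
    "effect_sd_fraction": 0.10,
    "effect_distribution": "normal",
    "schedule_params": {
      "target_mg": 2300,
      "elasticity": -0.1,
      "annual_cap": 0.20,
      "horizon_years": 10
    },
    "cost_nzd": 3680000,
    "cost_recurring": false,
    "cost_sd_fraction": 0.25,
    "cost_distribution": "gamma"
  },
  "sinking_lid": {
    "label": "Sinking lid on food-grade salt supply to a 2300 mg/d target",
    "mandatory": true,
    "schedule": "sinking_lid",
    "phase_years": 6,
    "effect_mean_mmol": null,
    "effect_sd_fraction": 0.10,
    "effect_distribution": "normal",
    "schedule_params": {
      "target_mg": 2300,
      "target_years": 6
    },
    "cost_nzd": 3680000,
    "cost_recurring": false,
    "cost_sd_fraction": 0.25,
    "cost_distribution": "gamma"
  }
}
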