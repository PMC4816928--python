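# Australian 5-arm profile: Daily Intake Guide, Traffic Lights,
# Health Star Rating, Warning Label, and the NIP control.
# All numeric tables are editable data; the shipped values are
# transcriptions in the style of the public labelling guides.
country: australia
arms: [DIG, TLL, HSR, WARNING, NIP]
baseline_days: 7
intervention_days: 28
run_in_min_items: 15
run_in_grace_days: 7
recruitment_window_days: 540
block_sizes: [5, 10]          # 1x and 2x the arm count
stratification: {}            # single (empty) stratum

screening:
  required_true: [age_18_plus, main_household_shopper, owns_smartphone]

schemes:
  traffic_light:
    # per 100 g (foods) / 100 mL (beverages); grams except sodium (mg)
    foods:
      fat: [3.0, 17.5]
      satfat: [1.5, 5.0]
      sugars: [5.0, 22.5]
      sodium: [120.0, 600.0]
    beverages:
      fat: [1.5, 8.75]
      satfat: [0.75, 2.5]
      sugars: [2.5, 11.25]
      sodium: [120.0, 300.0]
  daily_intake:
    energy_kj: 8700
    fat_g: 70
    satfat_g: 24
    sugars_g: 90
    sodium_mg: 2300
  hsr:
    # points = number of thresholds strictly exceeded (per 100 g/mL)
    foods:
      baseline:
        energy: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
        satfat: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        sugars: [5, 9, 13.5, 18, 22.5, 27, 31, 36, 40, 45]
        sodium: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
      modifying:
        fvnl: [40, 52, 63, 67, 75, 80, 90, 95]
        protein: [1.6, 3.2, 4.8, 6.4, 8.0, 9.6, 11.6, 13.9, 16.7, 20.0,
                  24.0, 28.9, 34.7, 41.6, 50.0]
        fibre: [0.9, 1.9, 2.8, 3.7, 4.7, 5.4, 6.3, 7.3, 8.4, 9.7,
                11.2, 13.0, 15.0, 16.8, 18.8]
      star_cutoffs: [-11, -6, -2, 2, 6, 10, 14, 18, 22]
    beverages:
      baseline:
        energy: [31, 66, 99, 132, 165, 198, 231, 264, 297, 330]
        satfat: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        sugars: [2.5, 4.5, 7, 9, 11.25, 13.5, 15.5, 18, 20, 22.5]
        sodium: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
      modifying:
        fvnl: [40, 52, 63, 67, 75, 80, 90, 95]
        protein: [1.6, 3.2, 4.8, 6.4, 8.0, 9.6, 11.6, 13.9, 16.7, 20.0,
                  24.0, 28.9, 34.7, 41.6, 50.0]
        fibre: [0.9, 1.9, 2.8, 3.7, 4.7, 5.4, 6.3, 7.3, 8.4, 9.7,
                11.2, 13.0, 15.0, 16.8, 18.8]
      star_cutoffs: [-6, -4, -2, 0, 2, 4, 7, 10, 13]
  warning:
    text: "HIGH IN"
    thresholds:      # strict '>' per 100 g/mL
      satfat: 5.0
      sugars: 22.5
      sodium: 600.0
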