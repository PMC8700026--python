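# Base-case scenario grid: four starting ages, three intervals, two
# care tiers, two perspectives, with the packaged parameter table and a
# life table calibrated to life expectancy 73.6 at birth.
ages: [30, 35, 40, 45]
intervals: ["one-off", "annual", "3-yearly"]
settings: ["CHS", "DHC"]
perspectives: ["societal", "provider"]
life_table_e0: 73.6
wtp: 2715.3
discount_rate: 0.03
max_age: 100
psa_n: 1000
seed: 12345
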