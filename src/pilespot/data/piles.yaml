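# Default six-pile monitoring campaign: reactor dimensions, probing heights,
# construction and sampling design.  Units: metres, days, megagrams.
#
# All piles share one aeration blower model (three channels under each pile)
# and the same sampling design: 4 cross-sections at fixed distances from the
# fan, 7 probe points per cross-section, weekly cycles.

fan:
  rotation_per_min: 3480
  back_pressure_Pa: 3800
  rate_of_delivery_m3_per_min: 51
  power_kW: 2.64
  n_channels: 3

piles:
  A1:
    probing_heights_m: [0.625, 1.250, 1.875]
    height_m: 2.5
    width_m: 8.1
    length_m: 50.0
    has_sidewalls: false
    covered: true
    n_cycles: 10
    n_cross_sections: 4
    cross_section_distances_m: [2.5, 17.5, 32.5, 47.5]
    n_points_per_cross_section: 7
    process_days: 69
  A2:
    probing_heights_m: [0.625, 1.250, 1.800]
    height_m: 2.1
    width_m: 8.0
    length_m: 50.0
    has_sidewalls: false
    covered: true
    n_cycles: 9
    n_cross_sections: 4
    cross_section_distances_m: [2.5, 17.5, 32.5, 47.5]
    n_points_per_cross_section: 7
    process_days: 66
  B1:
    probing_heights_m: [0.750, 1.500, 2.250]
    height_m: 2.8
    width_m: 8.4
    length_m: 50.0
    has_sidewalls: false
    covered: true
    n_cycles: 9
    n_cross_sections: 4
    cross_section_distances_m: [2.5, 17.5, 32.5, 47.5]
    n_points_per_cross_section: 7
    process_days: 62
  B2:
    probing_heights_m: [0.750, 1.500, 2.250]
    height_m: 2.9
    width_m: 9.0
    length_m: 50.0
    has_sidewalls: false
    covered: true
    n_cycles: 6
    n_cross_sections: 4
    cross_section_distances_m: [2.5, 17.5, 32.5, 47.5]
    n_points_per_cross_section: 7
    process_days: 44
  C1:
    probing_heights_m: [0.750, 1.500, 2.250]
    height_m: 2.6
    width_m: 8.0
    length_m: 50.0
    has_sidewalls: true
    covered: true
    n_cycles: 6
    n_cross_sections: 4
    cross_section_distances_m: [2.5, 17.5, 32.5, 47.5]
    n_points_per_cross_section: 7
    process_days: 44
  C2:
    probing_heights_m: [0.750, 1.500, 2.250]
    height_m: 2.5
    width_m: 8.0
    length_m: 50.0
    has_sidewalls: true
    covered: true
    n_cycles: 6
    n_cross_sections: 4
    cross_section_distances_m: [2.5, 17.5, 32.5, 47.5]
    n_points_per_cross_section: 7
    process_days: 42
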