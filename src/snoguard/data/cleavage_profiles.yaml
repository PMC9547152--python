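# Synthetic cleavage profiles for the packaged tRNA-Leu-TAA-like reference.
#
# The two base profiles emulate the snoRNA-knockdown (af25_low) and
# snoRNA-overexpression (af25_high) conditions as the extremes of the
# methylated fraction m.  Both share identical cut-site coordinates and base
# weights and differ only in m; the protection factor 7/13 multiplies the
# protected site's weight on methylated molecules.  With protected weight
# w_p = 1.0 and other weights summing W_o = 1.0, the expected share of the
# protected 47-64 fragment family among all tRFs is
#
#   share(m) = (1-m) * w_p/(W_o+w_p) + m * f*w_p/(W_o + f*w_p)
#
# which evaluates to exactly 50% at m = 0 (af25_low) and
# (7/13)/(1 + 7/13) = 7/20 = 35% at m = 1 (af25_high).
#
# The protected cut site ends at position 64, one nucleotide before the
# predicted 2'-O-methylation site at position 65 (cleavage immediately
# upstream of the mark).
#
# Stress variants scale total abundance only (hypoxia x2.0, oxidative x1.5,
# matching the observed directions of stress-induced expression increases);
# fragmentation structure is unchanged.

profiles:
  af25_low:
    parent_id: tRNA-Leu-TAA-synthetic
    intact_fraction: 0.70
    methylated_fraction: 0.0
    protection_factor: 0.5384615384615384
    methylation_position: 65
    end_jitter: 2
    abundance_multiplier: 1.0
    expected_protected_share_pct: 50.0
    cut_sites:
      - {start: 47, end: 64, weight: 1.0}
      - {start: 1, end: 18, weight: 0.55}
      - {start: 30, end: 47, weight: 0.45}

  af25_high:
    parent_id: tRNA-Leu-TAA-synthetic
    intact_fraction: 0.70
    methylated_fraction: 1.0
    protection_factor: 0.5384615384615384
    methylation_position: 65
    end_jitter: 2
    abundance_multiplier: 1.0
    expected_protected_share_pct: 35.0
    cut_sites:
      - {start: 47, end: 64, weight: 1.0}
      - {start: 1, end: 18, weight: 0.55}
      - {start: 30, end: 47, weight: 0.45}

  af25_low_hypoxia:
    parent_id: tRNA-Leu-TAA-synthetic
    intact_fraction: 0.70
    methylated_fraction: 0.0
    protection_factor: 0.5384615384615384
    methylation_position: 65
    end_jitter: 2
    abundance_multiplier: 2.0
    expected_protected_share_pct: 50.0
    cut_sites:
      - {start: 47, end: 64, weight: 1.0}
      - {start: 1, end: 18, weight: 0.55}
      - {start: 30, end: 47, weight: 0.45}

  af25_low_oxidative:
    parent_id: tRNA-Leu-TAA-synthetic
    intact_fraction: 0.70
    methylated_fraction: 0.0
    protection_factor: 0.5384615384615384
    methylation_position: 65
    end_jitter: 2
    abundance_multiplier: 1.5
    expected_protected_share_pct: 50.0
    cut_sites:
      - {start: 47, end: 64, weight: 1.0}
      - {start: 1, end: 18, weight: 0.55}
      - {start: 30, end: 47, weight: 0.45}

  af25_high_hypoxia:
    parent_id: tRNA-Leu-TAA-synthetic
    intact_fraction: 0.70
    methylated_fraction: 1.0
    protection_factor: 0.5384615384615384
    methylation_position: 65
    end_jitter: 2
    abundance_multiplier: 2.0
    expected_protected_share_pct: 35.0
    cut_sites:
      - {start: 47, end: 64, weight: 1.0}
      - {start: 1, end: 18, weight: 0.55}
      - {start: 30, end: 47, weight: 0.45}

  af25_high_oxidative:
    parent_id: tRNA-Leu-TAA-synthetic
    intact_fraction: 0.70
    methylated_fraction: 1.0
    protection_factor: 0.5384615384615384
    methylation_position: 65
    end_jitter: 2
    abundance_multiplier: 1.5
    expected_protected_share_pct: 35.0
    cut_sites:
      - {start: 47, end: 64, weight: 1.0}
      - {start: 1, end: 18, weight: 0.55}
      - {start: 30, end: 47, weight: 0.45}
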