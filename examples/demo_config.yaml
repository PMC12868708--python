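clustering:
  eps: 0.5
  min_pts: 5
  resolution: 1.0
ibd_between_rate: 0.05
ibd_communities:
- - comm-0
  - 40
- - comm-1
  - 40
- - comm-2
  - 40
- - comm-3
  - 40
- - comm-4
  - 40
ibd_within_rate: 2.0
observed_counts: null
outdir: hfemap_out
pc_groups:
- centroid:
  - 0.0
  - 0.0
  label: group-A
  n: 150
  spread: 0.3
- centroid:
  - 4.0
  - 0.0
  label: group-B
  n: 150
  spread: 0.3
- centroid:
  - 0.0
  - 4.0
  label: group-C
  n: 100
  spread: 0.3
pc_noise_box:
- -10
- 10
- -10
- 10
pc_noise_n: 20
penetrance:
  cmpd: 0.06
  hom: 0.56
  label: male, cumulative to age 80
regions:
  Birmingham:
    ascertainment: 0.297424
    n_individuals: 20000
    p_c282y: 0.072629
    p_h63d: 0.151
  Cheshire & Merseyside:
    ascertainment: 0.636531
    n_individuals: 20000
    p_c282y: 0.083523
    p_h63d: 0.151
  Cornwall:
    ascertainment: 0.360544
    n_individuals: 20000
    p_c282y: 0.074025
    p_h63d: 0.151
  E-Midlands:
    ascertainment: 0.404639
    n_individuals: 20000
    p_c282y: 0.068617
    p_h63d: 0.151
  East:
    ascertainment: 0.365385
    n_individuals: 20000
    p_c282y: 0.066051
    p_h63d: 0.151
  Lancashire & S Cumbria:
    ascertainment: 0.358095
    n_individuals: 20000
    p_c282y: 0.081988
    p_h63d: 0.151
  London:
    ascertainment: 0.518617
    n_individuals: 20000
    p_c282y: 0.067344
    p_h63d: 0.151
  Manchester:
    ascertainment: 0.402256
    n_individuals: 20000
    p_c282y: 0.082623
    p_h63d: 0.151
  North:
    ascertainment: 0.308285
    n_individuals: 20000
    p_c282y: 0.081441
    p_h63d: 0.151
  Southeast:
    ascertainment: 0.355191
    n_individuals: 20000
    p_c282y: 0.066268
    p_h63d: 0.151
  Southwest:
    ascertainment: 0.367978
    n_individuals: 20000
    p_c282y: 0.065178
    p_h63d: 0.151
  W-Midlands:
    ascertainment: 0.384798
    n_individuals: 20000
    p_c282y: 0.072023
    p_h63d: 0.151
  Yorkshire:
    ascertainment: 0.357602
    n_individuals: 20000
    p_c282y: 0.076563
    p_h63d: 0.151
round_to_5: true
seed: 0
top_k: 2

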