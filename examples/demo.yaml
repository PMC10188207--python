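# Demo run: one stage of each kind at small problem sizes.
# Execute from the repository root with:  foxptools run examples/demo.yaml
seed: 7
outdir: runs/demo
stages:
  - name: zip_lin_titration
    kind: titration
    construct: ZIP-lin
    kd_nm: 123.0
    max_nm: 5000.0
    noise_sd: 0.001
  - name: zip_lin_unfolding
    kind: unfolding
    construct: ZIP-lin
    mechanism: dimer2
    dg0: [10.0]
    m: [-4.0]
    baselines: [1.0, 0.0]
    p_total_nm: 200.0
    noise_sd: 0.02
    d_max: 3.0
  - name: free_protein
    kind: photons
    duration_s: 20.0
    burst_rate_hz: 60.0
    background_rate_hz: 300.0
    species:
      - fraction: 1.0
        lifetimes: [[1.0, 4.35]]
        r0: 0.38
        rotations: [[0.7, 0.2], [0.3, 60.0]]
  - name: free_protein_fcs
    kind: fcs
    input: free_protein
  - name: zip_landscape
    kind: landscape
    n_frames: 8000
    basins:
      - {weight: 0.5, rg: 12.0, f_alpha: 0.85}
      - {weight: 0.3, rg: 13.5, f_alpha: 0.60}
      - {weight: 0.2, rg: 20.0, f_alpha: 0.25}
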