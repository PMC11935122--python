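# Demo pipeline configuration: simulate -> rescale -> qc -> halluc -> structure
# on a 256 px field, 20-frame movie, 20 nm pixels, 4.6 s frame interval.
out_dir: demo_run
rng_seed: 1
height_px: 256
width_px: 256
pixel_size_nm: 20.0
frame_interval_s: 4.6
n_frames: 20
rearrangement_rate: 0.1
n_train_pairs: 4
n_seed_nodes: 40
n_sheets: 3
tube_width_nm: 100.0
psf_fwhm_nm: 90.0
dark_count_rate: 0.01
rolling_ball_radius_px: 15
rfrc_block_px: 64
rfrc_stride_px: 16
rfrc_background_intensity: 20.0
stages: [simulate, rescale, qc, halluc, structure]
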