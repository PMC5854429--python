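# Desk-scale demo: stage 1 of a two-stage unwrapping protocol on the
# bead-on-spool mimic (4 beads and 2 binding sites per arm).
stage_id = "stage1"
seed = 5

[system]
type = "mimic"

[system.spec]
n_beads = 4
n_sites = 2
site_energies = [0.8, 0.8]
site_beads = [0, 2]
friction = 0.5

[abmd]
range = [20.0, 90.0]
walls = [24.0, 86.0]
tau = 1.0
n_walkers = 8
duration = 120.0
record_interval = 20

[umbrella]
lo = 26.0
hi = 84.0
spacing = 2.0
k = 0.3
duration = 150.0
record_interval = 20
burn_in = 30.0

[wham]
bin_width = 1.0

[metrics]
count_mode = "any"
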