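# Published six-flock aviary layouts (one commercial house per flock).
# flock2 aisle widths are reconstructed: the published layout row is
# typographically garbled; the values below reproduce the printed
# per-transect bird counts but flock2 is excluded from golden layout tests.
house_id,house_width_m,n_structures,flock_size,usable_area_m2,floor_area_m2,aisle_widths
flock1,14.0,3,7500,1850,1000,1.75;1.75;1.75;1.75
flock2,12.0,3,7700,990,506,1.54;1.51;1.51;1.54
flock3,11.0,2,7840,915,432,1.11;1.11;1.11
flock4,10.0,1,7200,815,385,2.11;2.11
flock5,12.0,2,7500,1005,648,1.03;1.10;1.04
flock6,11.0,3,7500,910,450,1.40;1.49;1.49;1.40
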