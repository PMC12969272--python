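name,headgroup_class,tail_class,count_per_leaflet
DOPE,PE,MU,36
PYPE,PE,PU,8
YOPE,PE,MU,6
POPE,PE,sat,6
DYPE,PE,MU,2
DOPG,PG,MU,16
POPG,PG,sat,8
YPPG,PG,sat,2
DOPC,PC,MU,8
POPC,PC,sat,2
PYPC,PC,sat,2
TOCL,CL,MU,4
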