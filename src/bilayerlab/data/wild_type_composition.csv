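name,headgroup_class,tail_class,count_per_leaflet
DOPE,PE,MU,18
PYPE,PE,PU,4
YOPE,PE,MU,3
POPE,PE,sat,3
DYPE,PE,MU,1
DOPG,PG,MU,8
POPG,PG,sat,4
YPPG,PG,sat,1
DOPC,PC,MU,4
POPC,PC,sat,1
PYPC,PC,sat,1
TOCL,CL,MU,2
BHT-CE,HOP,none,25
BHT-GLU,HOP,none,25
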