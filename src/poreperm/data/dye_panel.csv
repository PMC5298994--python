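name,molecular_weight,net_charge,uptake_class,blocker_inhibited
ACMA,258.7,1,non_permeant,not_applicable
Methylene blue,319.8,1,permeant,yes
DAPI+2,350.2,2,permeant,yes
Ethidium bromide,394.3,1,permeant,yes
Hexidium iodide,497.4,1,permeant,yes
Nuclear yellow,651.0,1,non_permeant,not_applicable
Propidium iodide,668.3,2,non_permeant,not_applicable
Procion Orange MX2R,715.5,-3,permeant,yes
Indocyanine green,774.9,-1,permeant,yes
BBG,854.0,-1,non_permeant,not_applicable
Ethidium homodimer,856.7,4,non_permeant,not_applicable
Evans blue,960.8,-4,permeant,yes
BOBO-1 iodide,1202.6,4,non_permeant,not_applicable
7-AAD,1270.4,0,permeant,yes
YOYO-1 iodide,1270.7,4,permeant,yes
TOTO-1 iodide,1302.8,4,permeant,yes
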