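(((Vpol,((Tbla,Tpha),((Ndai,Ncas),((Knag,Kafr),(Cgla,(Suva,(Skud,(Smik,Scer))))))))WGD,(Zrou,Tdel)),((Klac,(Ecym,Egos)),(Lklu,(Lthe,Lwal))));
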