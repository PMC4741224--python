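<?xml version="1.0" encoding="UTF-8"?>
<!-- Treatment-level elements of the manuscript dialect (TaxPub-style
     extension elements in their own namespace). A nomenclature block holds
     one nomenclatural act; an optional registration-id in first position
     is the identifier injection point. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="http://www.plazi.org/taxpub"
           xmlns:tp="http://www.plazi.org/taxpub"
           elementFormDefault="qualified">

  <xs:element name="taxon-treatment">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="tp:nomenclature" maxOccurs="unbounded"/>
        <xs:element name="treatment-sec" type="xs:string"
                    minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="nomenclature">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="registration-id" type="xs:string" minOccurs="0"/>
        <xs:element ref="tp:taxon-name"/>
        <xs:element name="taxon-authority" type="xs:string" minOccurs="0"/>
        <xs:element name="taxon-status" type="xs:string"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="taxon-name">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="taxon-name-part" maxOccurs="unbounded">
          <xs:complexType>
            <xs:simpleContent>
              <xs:extension base="xs:string">
                <xs:attribute name="taxon-name-part-type" use="required">
                  <xs:simpleType>
                    <xs:restriction base="xs:string">
                      <xs:enumeration value="uninomial"/>
                      <xs:enumeration value="genus"/>
                      <xs:enumeration value="species"/>
                      <xs:enumeration value="infraspecific"/>
                    </xs:restriction>
                  </xs:simpleType>
                </xs:attribute>
              </xs:extension>
            </xs:simpleContent>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="hybrid">
        <xs:simpleType>
          <xs:restriction base="xs:string">
            <xs:enumeration value="yes"/>
            <xs:enumeration value="no"/>
          </xs:restriction>
        </xs:simpleType>
      </xs:attribute>
    </xs:complexType>
  </xs:element>

</xs:schema>
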